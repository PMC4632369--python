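import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_mature_family, make_pre_family, make_profile
from tdrkit.align import ErrorType, Placement
from tdrkit.naming import (classify_size, compute_coverage, mature_suffix,
                           name_primary, pre_suffix, primary_length)
from tdrkit.preprocess import UniqueRead
from tdrkit.reference import LoopBounds

MATURE76 = make_mature_family("ACGT" * 18 + "GCCA", name="Glu-CTC-1-7")  # 76 nt


def place(count, start, end, stage=ErrorType.EXACT_MATURE, mism=(), dels=(),
          family=MATURE76):
    span = end - start + 1
    read_len = span - len(dels)
    return (UniqueRead("A" * read_len, count), stage,
            Placement(family.name, start, span, tuple(mism), tuple(dels)))


class TestComputeCoverage:
    def test_count_weighted_fractions(self):
        profile = compute_coverage(MATURE76, [place(150, 1, 30), place(50, 40, 70)])
        assert profile.coverage[4] == 0.75      # position 5
        assert profile.coverage[49] == 0.25     # position 50
        assert profile.coverage[34] == 0.0      # position 35

    def test_single_read_covers_its_span_fully(self):
        profile = compute_coverage(MATURE76, [place(10, 5, 24)])
        assert profile.coverage[4:24].tolist() == [1.0] * 20
        assert profile.coverage[:4].sum() == 0 and profile.coverage[24:].sum() == 0

    def test_error_fraction_uses_spanning_reads_as_denominator(self):
        placed = [place(100, 1, 30),
                  place(25, 1, 30, stage=ErrorType.DEL1, dels=(8,))]
        profile = compute_coverage(MATURE76, placed)
        assert profile.error_fractions["del1"][7] == pytest.approx(0.2)  # 25/125
        assert profile.error_fractions["del3"][7] == 0.0

    def test_deleted_positions_count_as_covered(self):
        profile = compute_coverage(MATURE76, [place(10, 1, 21, stage=ErrorType.DEL1,
                                                    dels=(8,))])
        assert profile.coverage[7] == 1.0

    def test_del3_errors_tracked_separately(self):
        placed = [place(60, 1, 30),
                  place(40, 1, 33, stage=ErrorType.DEL3, dels=(6, 7, 8))]
        profile = compute_coverage(MATURE76, placed)
        assert profile.error_fractions["del3"][5] == pytest.approx(0.4)

    def test_zero_reads_is_an_error(self):
        with pytest.raises(ValueError):
            compute_coverage(MATURE76, [])

    def test_foreign_placement_rejected(self):
        foreign = place(10, 1, 20, family=make_mature_family("A" * 73 + "CCA",
                                                             name="Val-CAC-1-1"))
        with pytest.raises(ValueError):
            compute_coverage(MATURE76, [foreign])


class TestPrimaryLength:
    def test_uniform_block(self):
        assert primary_length(make_profile(76, {(1, 30): 1.0})) == 30

    def test_exactly_half_coverage_excluded(self):
        assert primary_length(make_profile(76, {(1, 76): 0.5})) == 0

    def test_half_overlapping_populations(self):
        # counts 100/100 over spans 1-30 and 15-44: only the 16-position
        # intersection 15-30 exceeds 50 %
        profile = compute_coverage(MATURE76, [place(100, 1, 30), place(100, 15, 44)])
        assert primary_length(profile) == 16


class TestClassifySize:
    @pytest.mark.parametrize("length,expected", [
        (28, "tRH"), (40, "tRH"), (27, "tRF"), (15, "tRF"),
        (14, "undefined"), (41, "undefined"), (0, "undefined")])
    def test_boundaries(self, length, expected):
        assert classify_size(length) == expected


class TestMatureSuffix:
    def test_five_prime_suppresses_d_and_a(self):
        assert mature_suffix(make_profile(76, {(1, 32): 1.0})) == "5′"

    def test_three_prime_suppresses_t_and_a(self):
        assert mature_suffix(make_profile(76, {(48, 76): 1.0})) == "3′"

    def test_d_loop_only(self):
        assert mature_suffix(make_profile(76, {(2, 30): 1.0})) == "D"

    def test_anticodon_loop_only(self):
        assert mature_suffix(make_profile(76, {(23, 50): 1.0})) == "A"

    def test_t_loop_only(self):
        assert mature_suffix(make_profile(76, {(40, 67): 1.0})) == "T"

    def test_da_composition(self):
        assert mature_suffix(make_profile(76, {(14, 44): 1.0})) == "DA"

    def test_dta_composition(self):
        assert mature_suffix(make_profile(76, {(14, 60): 1.0})) == "DTA"

    def test_full_length_coverage_emits_both_ends(self):
        assert mature_suffix(make_profile(76, {(1, 76): 1.0})) == "5′3′"

    def test_custom_loop_bounds_respected(self):
        bounds = LoopBounds(5, 8, 31, 39, -23, -15)
        assert mature_suffix(make_profile(76, {(4, 10): 1.0}), bounds) == "D"

    def test_too_short_profile_is_an_error(self):
        with pytest.raises(ValueError):
            mature_suffix(make_profile(20, {(1, 10): 1.0}))

    def test_pre_profile_rejected(self):
        with pytest.raises(ValueError):
            mature_suffix(make_profile(153, {(1, 20): 1.0}, kind="pre"))


class TestPreSuffix:
    # pre profiles: length 153, leader 1-40, body 41-113, trailer 114-153
    def test_trailer_only(self):
        assert pre_suffix(make_profile(153, {(114, 136): 1.0}, kind="pre")) == "1"

    def test_leader_only(self):
        assert pre_suffix(make_profile(153, {(18, 40): 1.0}, kind="pre")) == "0"

    def test_leader_into_body(self):
        assert pre_suffix(make_profile(153, {(30, 52): 1.0}, kind="pre")) == "0B"

    def test_body_into_trailer(self):
        assert pre_suffix(make_profile(153, {(95, 117): 1.0}, kind="pre")) == "1B"

    def test_body_only(self):
        assert pre_suffix(make_profile(153, {(50, 80): 1.0}, kind="pre")) == "B"


class TestNamePrimary:
    def test_low_dominance_is_undefined(self):
        profile = make_profile(76, {(1, 32): 0.60})
        named = name_primary(MATURE76, profile)
        assert named.full_name == "undefined"
        assert named.size_class == "undefined"
        assert named.max_coverage == pytest.approx(0.60)

    def test_exactly_two_thirds_is_still_undefined(self):
        profile = make_profile(76, {(1, 32): 2.0 / 3.0})
        assert name_primary(MATURE76, profile).full_name == "undefined"

    def test_dominant_five_prime_half(self):
        profile = make_profile(76, {(1, 32): 0.69})
        named = name_primary(MATURE76, profile)
        assert named.full_name == "Glu-CTC-1-7-tRH-5′"
        assert (named.size_class, named.location_suffix) == ("tRH", "5′")
        assert named.primary_length == 32

    def test_pre_trailer_fragment(self):
        pre = make_pre_family("A" * 153, name="pre-Arg-CTC-2-1.1")
        profile = make_profile(153, {(114, 133): 1.0}, kind="pre",
                               name="pre-Arg-CTC-2-1.1")
        named = name_primary(pre, profile)
        assert named.full_name == "pre-Arg-CTC-2-1.1-tRF-1"
        assert named.primary_length == 20

    def test_dominant_but_out_of_size_window_reports_undefined(self):
        profile = make_profile(76, {(1, 10): 0.9})  # 10 positions < 15
        named = name_primary(MATURE76, profile)
        assert named.full_name == "undefined"
        assert named.max_coverage == pytest.approx(0.9)


coverage_arrays = st.lists(
    st.sampled_from([0.0, 0.3, 0.55, 0.8, 1.0]), min_size=76, max_size=76)


@given(coverage_arrays)
def test_suffix_exclusion_rules_never_violated(values):
    profile = make_profile(76, {})
    profile.coverage = np.array(values)
    suffix = mature_suffix(profile)
    if "5′" in suffix:
        assert "D" not in suffix and "A" not in suffix
    if "3′" in suffix:
        assert "A" not in suffix and "T" not in suffix


@given(coverage_arrays, st.integers(0, 75))
def test_primary_length_monotone_in_coverage(values, idx):
    profile = make_profile(76, {})
    profile.coverage = np.array(values)
    before = primary_length(profile)
    boosted = np.array(values)
    boosted[idx] = min(1.0, boosted[idx] + 0.5)
    profile.coverage = boosted
    assert primary_length(profile) >= before
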