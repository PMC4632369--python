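import logging
import random

import pytest
from hypothesis import given, strategies as st

from tdrkit.reference import (DEFAULT_LOOP_BOUNDS, LoopBounds, TRNAGene,
                              build_mature_library, build_pre_library,
                              generalized_loop_bounds, load_library,
                              read_genes, write_genes, write_library)

FLANK = "A" * 40


def gene(gene_id="g1", aa="Gly", ac="GCC", fam=1, copy=1, body="ACGT" * 18,
         introns=(), flank5=FLANK, flank3=FLANK):
    return TRNAGene(gene_id, aa, ac, fam, copy, body, list(introns), flank5, flank3)


class TestMatureLibrary:
    def test_cca_appended_without_intron(self):
        fams = build_mature_library([gene(body="GCATTGGCC")])
        assert fams[0].sequence == "GCATTGGCCCCA"

    def test_intron_excised_before_cca(self):
        fams = build_mature_library([gene(body="AAAAACCCCCGGGGG", introns=[(6, 10)])])
        assert fams[0].sequence == "AAAAAGGGGGCCA"

    def test_family_name_counts_identical_gene_copies(self):
        genes = [gene(gene_id=f"g{i}", aa="Asp", ac="GTC", fam=2, copy=i)
                 for i in range(1, 12)]
        fams = build_mature_library(genes)
        assert len(fams) == 1
        assert fams[0].name == "Asp-GTC-2-11"
        assert len(fams[0].member_gene_ids) == 11

    def test_each_gene_lands_in_exactly_one_family(self):
        genes = ([gene(gene_id=f"a{i}", aa="Asp", ac="GTC", copy=i, body="ACGT" * 18)
                  for i in range(1, 4)]
                 + [gene(gene_id="b1", aa="Gly", ac="TCC", body="TTGCA" * 15)])
        fams = build_mature_library(genes)
        z_sum = sum(len(f.member_gene_ids) for f in fams)
        assert z_sum == len(genes)
        assert all(f.sequence.endswith("CCA") for f in fams)

    def test_order_independent(self):
        genes = [gene(gene_id=f"g{i}", aa=aa, ac="GCC", fam=1, copy=c, body=body)
                 for i, (aa, c, body) in enumerate([
                     ("Gly", 1, "ACGT" * 18), ("Gly", 2, "ACGT" * 18),
                     ("Val", 1, "TGCA" * 18)])]
        baseline = build_mature_library(genes)
        for _ in range(5):
            random.Random(1).shuffle(genes)
            assert build_mature_library(genes) == baseline

    def test_same_family_metadata_with_diverged_sequences_is_an_error(self):
        genes = [gene(gene_id="g1", copy=1, body="ACGT" * 18),
                 gene(gene_id="g2", copy=2, body="TGCA" * 18)]
        with pytest.raises(ValueError, match="g1"):
            build_mature_library(genes)

    def test_duplicate_copy_index_is_an_error(self):
        genes = [gene(gene_id="g1", copy=1), gene(gene_id="g2", copy=1)]
        with pytest.raises(ValueError, match="copy_index"):
            build_mature_library(genes)

    def test_identical_sequence_distinct_metadata_kept_separate(self, caplog):
        genes = [gene(gene_id="g1", aa="Gly", ac="GCC"),
                 gene(gene_id="g2", aa="Gly", ac="TCC")]
        with caplog.at_level(logging.WARNING):
            fams = build_mature_library(genes)
        assert len(fams) == 2
        assert "not merged" in caplog.text


class TestPreLibrary:
    def test_grouped_name_uses_largest_copy_index(self):
        genes = [gene(gene_id=f"g{i}", aa="Gly", ac="TCC", fam=2, copy=i)
                 for i in (2, 3, 4, 5)]
        fams = build_pre_library(genes)
        assert len(fams) == 1
        assert fams[0].name == "pre-Gly-TCC-2-5.4"

    def test_singleton_gets_own_copy_index_and_suffix_one(self):
        fams = build_pre_library([gene(copy=3)])
        assert fams[0].name == "pre-Gly-GCC-1-3.1"

    def test_pre_length_and_body_bounds(self):
        fams = build_pre_library([gene(body="G" * 72)])
        assert len(fams[0].sequence) == 152
        assert (fams[0].body_start, fams[0].body_end) == (41, 112)

    def test_intron_retained_in_pre_sequence(self):
        g = gene(body="AAAAACCCCCGGGGG", introns=[(6, 10)])
        fams = build_pre_library([g])
        assert fams[0].sequence == FLANK + "AAAAACCCCCGGGGG" + FLANK

    def test_distinct_flanks_split_pre_families(self):
        genes = [gene(gene_id="g1", copy=1),
                 gene(gene_id="g2", copy=2, flank3="C" * 40)]
        fams = build_pre_library(genes)
        assert len(fams) == 2
        assert sorted(f.name for f in fams) == ["pre-Gly-GCC-1-1.1", "pre-Gly-GCC-1-2.1"]


class TestGeneValidation:
    def test_flank_length_enforced(self):
        with pytest.raises(ValueError, match="flank5"):
            gene(flank5="A" * 39)

    def test_intron_outside_body_rejected(self):
        with pytest.raises(ValueError, match="intron"):
            gene(body="ACGTACGTACGTAC", introns=[(10, 20)])

    def test_non_dna_characters_rejected(self):
        with pytest.raises(ValueError, match="non-DNA"):
            gene(body="ACGU" * 18)


class TestLoopBounds:
    def test_mode_of_annotated_positions(self):
        structures = [LoopBounds(13, 22, 31, 39, -23, -15),
                      LoopBounds(13, 22, 31, 39, -23, -15),
                      LoopBounds(14, 23, 32, 40, -22, -14)]
        assert generalized_loop_bounds(structures).d_start == 13

    def test_defaults_without_annotations(self):
        assert generalized_loop_bounds(None) == LoopBounds(13, 22, 31, 39, -23, -15)
        assert generalized_loop_bounds([]) == DEFAULT_LOOP_BOUNDS

    def test_identical_annotations_returned_unchanged(self):
        lb = LoopBounds(12, 21, 30, 38, -24, -16)
        assert generalized_loop_bounds([lb, lb, lb]) == lb

    def test_tie_resolves_to_smallest_with_warning(self, caplog):
        structures = [LoopBounds(13, 22, 31, 39, -23, -15),
                      LoopBounds(14, 22, 31, 39, -23, -15)]
        with caplog.at_level(logging.WARNING):
            assert generalized_loop_bounds(structures).d_start == 13
        assert "multimodal" in caplog.text


@given(st.permutations(list(range(6))))
def test_mature_library_invariant_under_gene_order(order):
    bodies = ["ACGT" * 18, "ACGT" * 18, "TGCA" * 18, "GGCC" * 18, "GGCC" * 18, "ATTA" * 18]
    metas = [("Gly", 1, 1), ("Gly", 1, 2), ("Val", 1, 1), ("Asp", 1, 1), ("Asp", 1, 2), ("His", 1, 1)]
    genes = [gene(gene_id=f"g{i}", aa=metas[i][0], fam=metas[i][1],
                  copy=metas[i][2], body=bodies[i]) for i in range(6)]
    shuffled = [genes[i] for i in order]
    assert build_mature_library(shuffled) == build_mature_library(genes)
    assert build_pre_library(shuffled) == build_pre_library(genes)


def test_gene_and_library_round_trip(tmp_path):
    genes = [gene(gene_id="g1", body="ACGTT" * 15, introns=[(6, 10)]),
             gene(gene_id="g2", aa="Val", ac="CAC", copy=1, body="TTGCA" * 15,
                  flank3="G" * 40)]
    write_genes(genes, tmp_path / "bodies.fa", tmp_path / "genes.tsv")
    back = read_genes(tmp_path / "bodies.fa", tmp_path / "genes.tsv")
    assert [g.body_sequence for g in back] == [g.body_sequence for g in genes]
    assert back[0].intron_intervals == [(6, 10)]

    mature = build_mature_library(genes)
    write_library(mature, tmp_path / "mature.fa")
    loaded = load_library(tmp_path / "mature.fa", "mature")
    assert [(f.name, f.sequence) for f in loaded] == [(f.name, f.sequence) for f in mature]
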