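"""Per-family coverage profiles and the positional tDR naming grammar.

A tRNA family's reads are summarised as a positional coverage profile:
coverage at position p is the count-weighted fraction of the family's mapped
reads whose placement spans p (deleted reference positions included — the
read physically derives from across them).  The dominant ("primary") tDR of
the family is then named from the profile:

* size class — the number of positions with coverage > 50 % gives the
  primary tDR length L: a tRNA-half (tRH) for 28 <= L <= 40, a
  tRNA-fragment (tRF) for 15 <= L <= 27, otherwise undefined;
* location suffix — for mature families, membership of the > 50 % region in
  the 5' end (position +1), 3' end (position -7, to tolerate the tapering
  3' signal), D-loop, anticodon loop and T-loop windows; for pre families,
  leader ("0"), trailer ("1") and body ("B") regions;
* a primary tDR is only called at all when some position's coverage exceeds
  2/3 (strictly) — otherwise no single tDR clearly dominates and the family
  is reported as "undefined".

Negative coordinates count from the 3' end: -1 is the final base (the last A
of the appended CCA for mature families).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import ErrorType, Placement
from .preprocess import UniqueRead
from .reference import DEFAULT_LOOP_BOUNDS, LoopBounds, TRNAFamily

log = logging.getLogger(__name__)

ERROR_CLASSES = ("mismatch", "del1", "del3")
DOMINANCE_THRESHOLD = 2.0 / 3.0

FIVE_PRIME = "5′"
THREE_PRIME = "3′"


@dataclass
class CoverageProfile:
    """Positional coverage and error-class fractions for one family.

    ``coverage[p-1]`` is the fraction of the family's read count spanning
    position p.  ``error_fractions[cls][p-1]`` is the fraction of reads
    *spanning p* that carry an error of that class exactly at p (mismatches;
    single-base deletions from the DEL1/DEL2 stages; three-base-gap
    deletions from DEL3).
    """

    family_name: str
    kind: str
    length: int
    coverage: np.ndarray
    error_fractions: dict[str, np.ndarray]
    total_count: int
    body_start: int
    body_end: int

    @property
    def max_coverage(self) -> float:
        return float(self.coverage.max())


@dataclass(frozen=True)
class PrimaryTDR:
    """The named dominant tDR of one family (or "undefined")."""

    family_name: str
    size_class: str  # "tRH" | "tRF" | "undefined"
    location_suffix: str
    full_name: str
    primary_length: int
    max_coverage: float


def compute_coverage(family: TRNAFamily,
                     placed: Sequence[tuple[UniqueRead, ErrorType, Placement]],
                     ) -> CoverageProfile:
    """Build the coverage profile of one family from its read placements."""
    if not placed:
        raise ValueError(f"{family.name}: coverage profile requires at least one placed read")
    for _read, _stage, p in placed:
        if p.family_name != family.name:
            raise ValueError(f"placement for {p.family_name} passed to family {family.name}")
    n = len(family.sequence)
    span_counts = np.zeros(n, dtype=float)
    err_counts = {cls: np.zeros(n, dtype=float) for cls in ERROR_CLASSES}
    total = 0
    for read, stage, p in placed:
        total += read.count
        span_counts[p.ref_start - 1 : p.ref_end] += read.count
        for pos in p.mismatch_positions:
            err_counts["mismatch"][pos - 1] += read.count
        del_cls = "del3" if stage is ErrorType.DEL3 else "del1"
        for pos in p.deletion_positions:
            err_counts[del_cls][pos - 1] += read.count
    coverage = span_counts / total
    fractions = {}
    for cls, counts in err_counts.items():
        with np.errstate(invalid="ignore"):
            frac = np.where(span_counts > 0, counts / np.where(span_counts > 0, span_counts, 1), 0.0)
        fractions[cls] = frac
    return CoverageProfile(family.name, family.kind, n, coverage, fractions,
                           total, family.body_start, family.body_end)


def primary_length(profile: CoverageProfile) -> int:
    """Number of positions with coverage strictly above 50 %."""
    return int((profile.coverage > 0.5).sum())


def classify_size(length: int) -> str:
    """tRH for 28-40 nt, tRF for 15-27 nt, undefined outside those windows."""
    if 28 <= length <= 40:
        return "tRH"
    if 15 <= length <= 27:
        return "tRF"
    return "undefined"


def _resolve(pos: int, length: int) -> int:
    """Map a negative 3'-anchored coordinate (-1 = last base) to 1-based."""
    return pos if pos > 0 else length + 1 + pos


def mature_suffix(profile: CoverageProfile, bounds: LoopBounds = DEFAULT_LOOP_BOUNDS) -> str:
    """Location suffix for a mature-family tDR.

    Rules (cov means coverage > 50 %): "5'" if cov at position +1; "3'" if
    cov at position -7; "D" if cov anywhere in the D-loop window and not at
    +1; "A" if cov anywhere in the anticodon-loop window and not at +1 nor
    -7; "T" if cov anywhere in the T-loop window (3'-anchored) and not at
    -7.  Applicable letters concatenate in the fixed order 5', D, T, A, 3'.
    """
    if profile.kind != "mature":
        raise ValueError("mature_suffix applies to mature families only")
    n = profile.length
    t_lo, t_hi = _resolve(bounds.t_start, n), _resolve(bounds.t_end, n)
    if n < bounds.a_end or t_lo < 1:
        raise ValueError(f"{profile.family_name}: sequence of length {n} shorter "
                         f"than the loop coordinate windows")
    hot = profile.coverage > 0.5

    def window_hot(lo: int, hi: int) -> bool:
        return bool(hot[lo - 1 : hi].any())

    at_start = bool(hot[0])
    at_minus7 = bool(hot[_resolve(-7, n) - 1])
    has_d = window_hot(bounds.d_start, bounds.d_end) and not at_start
    has_a = window_hot(bounds.a_start, bounds.a_end) and not at_start and not at_minus7
    has_t = window_hot(t_lo, t_hi) and not at_minus7

    parts = []
    if at_start:
        parts.append(FIVE_PRIME)
    if has_d:
        parts.append("D")
    if has_t:
        parts.append("T")
    if has_a:
        parts.append("A")
    if at_minus7:
        parts.append(THREE_PRIME)
    if at_start and at_minus7:
        log.warning("%s: coverage >50%% at both ends; emitting combined suffix %s",
                    profile.family_name, "".join(parts))
    return "".join(parts)


def pre_suffix(profile: CoverageProfile) -> str:
    """Location suffix for a pre-family tDR: "0" for leader coverage, "1" for
    trailer coverage, "B" for body coverage, concatenated in that order."""
    if profile.kind != "pre":
        raise ValueError("pre_suffix applies to pre families only")
    hot = profile.coverage > 0.5
    leader = bool(hot[: profile.body_start - 1].any())
    trailer = bool(hot[profile.body_end :].any())
    body = bool(hot[profile.body_start - 1 : profile.body_end].any())
    return ("0" if leader else "") + ("1" if trailer else "") + ("B" if body else "")


def name_primary(family: TRNAFamily, profile: CoverageProfile,
                 bounds: LoopBounds = DEFAULT_LOOP_BOUNDS) -> PrimaryTDR:
    """Name the family's primary tDR, or report it "undefined" when no
    position's coverage exceeds 2/3 (no clearly dominant tDR) or when the
    primary length falls outside both size-class windows."""
    max_cov = profile.max_coverage
    length = primary_length(profile)
    if not max_cov > DOMINANCE_THRESHOLD:
        return PrimaryTDR(family.name, "undefined", "", "undefined", length, max_cov)
    size = classify_size(length)
    if size == "undefined":
        return PrimaryTDR(family.name, "undefined", "", "undefined", length, max_cov)
    suffix = mature_suffix(profile, bounds) if profile.kind == "mature" else pre_suffix(profile)
    if suffix:
        full = f"{family.name}-{size}-{suffix}"
    else:
        # dominant region touches none of the positional windows; keep the
        # size class but no location letter
        log.warning("%s: dominant region matches no location rule", family.name)
        full = f"{family.name}-{size}"
    return PrimaryTDR(family.name, size, suffix, full, length, max_cov)


def write_profile_tsv(profile: CoverageProfile, sequence: str, path: str | Path) -> None:
    """Per-family profile TSV: position, reference base, coverage and one
    column per error-class fraction."""
    with open(path, "w") as fh:
        fh.write("position\tbase\tcoverage\t" + "\t".join(ERROR_CLASSES) + "\n")
        for i in range(profile.length):
            errs = "\t".join(f"{profile.error_fractions[c][i]:.6g}" for c in ERROR_CLASSES)
            fh.write(f"{i + 1}\t{sequence[i]}\t{profile.coverage[i]:.6g}\t{errs}\n")
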