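"""Hierarchical error-tolerant alignment of unique reads to tRNA families.

Mature tRNAs carry extensive chemical modifications; during cDNA synthesis
these cause reverse-transcriptase mis-incorporation and skips, which show up
in small RNA-seq reads as mismatches and deletions relative to the reference.
Rather than scoring these as generic alignment errors, each read is assigned
to the *first* stage of a fixed "error type" hierarchy at which it aligns to
at least one reference family:

    EXACT_MATURE -> EXACT_PRE -> MM1 -> DEL1 -> MM2 -> DEL2 -> DEL3

Exact matching is attempted against mature then pre-tRNA libraries; the
error-tolerant stages run against mature tRNAs only (pre-tRNAs are assumed
not to be extensively modified).  MM1/MM2 allow exactly one/two substitutions;
DEL1/DEL2 allow exactly one/two reference bases skipped by the read; DEL3 is
a single contiguous three-base skip.  Insertions are not modelled.  Alignment
is end-to-end (no clipping) on the sense strand.

A read may place in several families at its stage; every such placement is
kept and later counted with the read's full copy count.  Within one family
only the best window survives: fewest errors, then leftmost start, then the
lexicographically smallest error-position set.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import UniqueRead
from .reference import TRNAFamily


class ErrorType(enum.Enum):
    """One stage of the alignment hierarchy; declaration order is dispatch
    order.  Fields: target library kind, mismatch budget, deletion budget,
    whether deletions must be contiguous."""

    EXACT_MATURE = ("mature", 0, 0, False)
    EXACT_PRE = ("pre", 0, 0, False)
    MM1 = ("mature", 1, 0, False)
    DEL1 = ("mature", 0, 1, False)
    MM2 = ("mature", 2, 0, False)
    DEL2 = ("mature", 0, 2, False)
    DEL3 = ("mature", 0, 3, True)

    def __init__(self, target_kind: str, n_mismatches: int, n_deletions: int,
                 contiguous: bool):
        self.target_kind = target_kind
        self.n_mismatches = n_mismatches
        self.n_deletions = n_deletions
        self.contiguous = contiguous


DEFAULT_STAGE_ORDER: tuple[ErrorType, ...] = tuple(ErrorType)


@dataclass(frozen=True)
class Placement:
    """Where a read sits on one family sequence.

    ``ref_start`` is 1-based; ``ref_span`` is the number of reference bases
    consumed (read length + number of deletions).  Error positions are
    1-based reference coordinates; deletions are reference bases absent from
    the read.
    """

    family_name: str
    ref_start: int
    ref_span: int
    mismatch_positions: tuple[int, ...] = ()
    deletion_positions: tuple[int, ...] = ()

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span - 1


@dataclass(frozen=True)
class AlignmentAssignment:
    """A mapped read: its hierarchy stage and one placement per family."""

    read: UniqueRead
    stage: ErrorType
    placements: tuple[Placement, ...]


@dataclass
class AlignmentResult:
    assignments: list[AlignmentAssignment]
    unmapped: list[UniqueRead]


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_scan(read_seq: str, ref: str, k: int) -> tuple[int, tuple[int, ...]] | None:
    """Leftmost window of len(read) with exactly k mismatches; returns
    (0-based start, 1-based mismatch reference positions)."""
    L = len(read_seq)
    if len(ref) < L:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(_seq_array(ref), L)
    neq = windows != _seq_array(read_seq)
    counts = neq.sum(axis=1)
    hits = np.nonzero(counts == k)[0]
    if hits.size == 0:
        return None
    s = int(hits[0])
    positions = tuple(int(p) + s + 1 for p in np.nonzero(neq[s])[0])
    return s, positions


def _is_subsequence(read_seq: str, window: str) -> bool:
    it = iter(window)
    return all(ch in it for ch in read_seq)


def _deletion_scan(read_seq: str, ref: str, k: int, contiguous: bool,
                   ) -> tuple[int, tuple[int, ...]] | None:
    """Leftmost window of len(read)+k from which deleting exactly k reference
    bases (a contiguous run when required) reproduces the read; within the
    window the lexicographically smallest deletion set is reported."""
    L = len(read_seq)
    width = L + k
    for s in range(len(ref) - width + 1):
        window = ref[s : s + width]
        if not _is_subsequence(read_seq, window):
            continue
        if contiguous:
            for g in range(L + 1):
                if window[:g] + window[g + k :] == read_seq:
                    return s, tuple(range(s + g + 1, s + g + k + 1))
        else:
            for combo in itertools.combinations(range(width), k):
                kept = [window[i] for i in range(width) if i not in combo]
                if "".join(kept) == read_seq:
                    return s, tuple(s + i + 1 for i in combo)
    return None


def find_placements(read_seq: str, family: TRNAFamily, stage: ErrorType) -> list[Placement]:
    """Best placement of ``read_seq`` on ``family`` under ``stage``'s exact
    error budget (empty list if none, or if the family kind does not match
    the stage's target library)."""
    if family.kind != stage.target_kind:
        return []
    L = len(read_seq)
    if stage.n_deletions == 0:
        if stage.n_mismatches == 0:
            idx = family.sequence.find(read_seq)
            if idx < 0:
                return []
            return [Placement(family.name, idx + 1, L)]
        hit = _mismatch_scan(read_seq, family.sequence, stage.n_mismatches)
        if hit is None:
            return []
        s, positions = hit
        return [Placement(family.name, s + 1, L, mismatch_positions=positions)]
    hit = _deletion_scan(read_seq, family.sequence, stage.n_deletions, stage.contiguous)
    if hit is None:
        return []
    s, positions = hit
    return [Placement(family.name, s + 1, L + stage.n_deletions,
                      deletion_positions=positions)]


def run_hierarchy(reads: Sequence[UniqueRead],
                  mature_lib: Sequence[TRNAFamily],
                  pre_lib: Sequence[TRNAFamily],
                  stage_order: Sequence[ErrorType] = DEFAULT_STAGE_ORDER,
                  ) -> AlignmentResult:
    """Assign every read to the first hierarchy stage at which it places in
    at least one family; reads exhausting all stages are recorded unmapped.

    The output is sorted by descending count then sequence, so results do not
    depend on input order.
    """
    libs = {"mature": list(mature_lib), "pre": list(pre_lib)}
    assignments: list[AlignmentAssignment] = []
    unmapped: list[UniqueRead] = []
    for read in sorted(reads, key=lambda u: (-u.count, u.sequence)):
        assigned = False
        for stage in stage_order:
            placements: list[Placement] = []
            for family in libs[stage.target_kind]:
                placements.extend(find_placements(read.sequence, family, stage))
            if placements:
                assignments.append(AlignmentAssignment(read, stage, tuple(placements)))
                assigned = True
                break
        if not assigned:
            unmapped.append(read)
    return AlignmentResult(assignments, unmapped)


def group_by_family(assignments: Sequence[AlignmentAssignment],
                    ) -> dict[str, list[tuple[UniqueRead, ErrorType, Placement]]]:
    """Regroup read assignments by the family each placement targets."""
    grouped: dict[str, list[tuple[UniqueRead, ErrorType, Placement]]] = {}
    for a in assignments:
        for p in a.placements:
            grouped.setdefault(p.family_name, []).append((a.read, a.stage, p))
    return grouped


def dump_assignments(result: AlignmentResult, path) -> None:
    """Per-read assignment TSV: sequence, count, stage, family, ref_start,
    error positions (semicolon-joined)."""
    with open(path, "w") as fh:
        fh.write("sequence\tcount\tstage\tfamily\tref_start\tmismatches\tdeletions\n")
        for a in result.assignments:
            for p in a.placements:
                fh.write(f"{a.read.sequence}\t{a.read.count}\t{a.stage.name}\t"
                         f"{p.family_name}\t{p.ref_start}\t"
                         f"{';'.join(map(str, p.mismatch_positions))}\t"
                         f"{';'.join(map(str, p.deletion_positions))}\n")
        for u in result.unmapped:
            fh.write(f"{u.sequence}\t{u.count}\tUNMAPPED\t\t\t\t\n")
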