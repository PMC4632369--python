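"""Construction of mature and pre-tRNA reference libraries.

Small RNAs derived from tRNAs cannot be mapped to the genome directly: mature
tRNAs are spliced, trimmed and carry a non-templated 3' CCA, and many tRNA
genes exist in several identical genomic copies.  This module therefore builds
two dedicated reference libraries from annotated tRNA genes:

* the **mature** library — intron-excised gene bodies with ``CCA`` appended;
* the **pre** library — the unspliced genomic transcript with 40 nt of
  genomic flank on either side (a proxy for the 5' leader and 3' trailer).

Genes producing identical sequences are aggregated into *families* so that a
read multi-mapping across identical gene copies has a single reference target.
Family names follow the ``W-X-Y-Z`` convention (amino acid, anticodon, family
identifier, number of identical gene copies); pre-tRNA families are named
``pre-W-X-Y-Z.n`` where ``Z`` is the largest member copy index and ``n`` the
number of members.

All coordinates in this module are 1-based closed intervals.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

FLANK_LENGTH = 40
_DNA = set("ACGTN")


@dataclass(frozen=True)
class LoopBounds:
    """Generalized positions of the three tRNA cloverleaf loops.

    D- and anticodon-loop bounds are counted from the 5' end (1-based);
    T-loop bounds are counted from the 3' end using negative coordinates
    (-1 = last base), because the variable loop makes 5'-anchored T-loop
    positions unstable across tRNAs.
    """

    d_start: int = 13
    d_end: int = 22
    a_start: int = 31
    a_end: int = 39
    t_start: int = -23
    t_end: int = -15

    def __post_init__(self) -> None:
        if not (self.d_start <= self.d_end and self.a_start <= self.a_end):
            raise ValueError("loop start must not exceed loop end")
        if not (self.t_start <= self.t_end <= -1):
            raise ValueError("T-loop bounds must be negative with start <= end")


DEFAULT_LOOP_BOUNDS = LoopBounds()


@dataclass
class TRNAGene:
    """One annotated tRNA gene: the raw material for both libraries.

    ``body_sequence`` is the full-length gene sequence as annotated, intron
    included; ``intron_intervals`` are 1-based closed intervals within it.
    ``flank5``/``flank3`` are the 40 nt of genomic sequence on either side.
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    family_index: int
    copy_index: int
    body_sequence: str
    intron_intervals: list[tuple[int, int]] = field(default_factory=list)
    flank5: str = ""
    flank3: str = ""
    loop_bounds: LoopBounds | None = None

    def __post_init__(self) -> None:
        self.body_sequence = self.body_sequence.upper()
        self.flank5 = self.flank5.upper()
        self.flank3 = self.flank3.upper()
        for name, seq in (("body_sequence", self.body_sequence),
                          ("flank5", self.flank5), ("flank3", self.flank3)):
            bad = set(seq) - _DNA
            if bad:
                raise ValueError(f"{self.gene_id}: {name} contains non-DNA characters {sorted(bad)}")
        for fname, seq in (("flank5", self.flank5), ("flank3", self.flank3)):
            if len(seq) != FLANK_LENGTH:
                raise ValueError(
                    f"{self.gene_id}: {fname} must be exactly {FLANK_LENGTH} nt, got {len(seq)}")
        if self.family_index < 1 or self.copy_index < 1:
            raise ValueError(f"{self.gene_id}: family_index and copy_index must be positive")
        n = len(self.body_sequence)
        last = 0
        for start, end in sorted(self.intron_intervals):
            if not (1 <= start <= end <= n):
                raise ValueError(f"{self.gene_id}: intron [{start},{end}] outside body 1..{n}")
            if start <= last:
                raise ValueError(f"{self.gene_id}: overlapping intron intervals")
            last = end
        self.intron_intervals = sorted(self.intron_intervals)

    @property
    def wxy(self) -> tuple[str, str, int]:
        return (self.amino_acid, self.anticodon, self.family_index)

    def mature_sequence(self) -> str:
        """Intron-excised body with the non-templated 3' CCA appended."""
        seq = self.body_sequence
        for start, end in reversed(self.intron_intervals):
            seq = seq[: start - 1] + seq[end:]
        return seq + "CCA"

    def pre_sequence(self) -> str:
        """The unspliced genomic transcript: flank + body (intron kept) + flank."""
        return self.flank5 + self.body_sequence + self.flank3


@dataclass(frozen=True)
class TRNAFamily:
    """A deduplicated reference sequence shared by one or more tRNA genes.

    ``body_start``/``body_end`` delimit the tRNA body within ``sequence``
    (1-based, closed): the whole sequence for mature families, positions
    41..len-40 for pre families.
    """

    name: str
    kind: str  # "mature" | "pre"
    sequence: str
    member_gene_ids: tuple[str, ...]
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.kind not in ("mature", "pre"):
            raise ValueError(f"unknown family kind {self.kind!r}")
        if self.kind == "mature":
            if self.body_start != 1 or self.body_end != len(self.sequence):
                raise ValueError(f"{self.name}: mature body must span the whole sequence")
            if not self.sequence.endswith("CCA"):
                raise ValueError(f"{self.name}: mature sequence must end in CCA")
        else:
            if self.body_start != FLANK_LENGTH + 1 or self.body_end != len(self.sequence) - FLANK_LENGTH:
                raise ValueError(f"{self.name}: pre body must be flanked by {FLANK_LENGTH} nt")


def _check_copy_indices(genes: Sequence[TRNAGene]) -> None:
    for wxy, members in _group_by_wxy(genes).items():
        seen = Counter(g.copy_index for g in members)
        dups = [c for c, k in seen.items() if k > 1]
        if dups:
            ids = sorted(g.gene_id for g in members if g.copy_index in dups)
            raise ValueError(
                f"conflicting metadata: duplicate copy_index {sorted(dups)} within "
                f"family {'-'.join(map(str, wxy))} (genes {ids})")


def _group_by_wxy(genes: Sequence[TRNAGene]) -> dict[tuple[str, str, int], list[TRNAGene]]:
    groups: dict[tuple[str, str, int], list[TRNAGene]] = defaultdict(list)
    for g in genes:
        groups[g.wxy].append(g)
    return groups


def build_mature_library(genes: Sequence[TRNAGene]) -> list[TRNAFamily]:
    """Aggregate genes with identical mature sequence (and identical W-X-Y
    metadata) into mature families named ``W-X-Y-Z``, Z = member count.

    Genes in the same W-X-Y group must all yield the same mature sequence —
    the family identifier Y denotes a sequence family, so disagreement is a
    hard error.  Identical sequences under *different* W-X-Y metadata are kept
    as separate families (with a warning) to preserve the naming scheme.
    """
    _check_copy_indices(genes)
    families: list[TRNAFamily] = []
    for (w, x, y), members in sorted(_group_by_wxy(genes).items()):
        seqs = {g.mature_sequence() for g in members}
        if len(seqs) > 1:
            ids = sorted(g.gene_id for g in members)
            raise ValueError(
                f"conflicting metadata: genes {ids} share family {w}-{x}-{y} "
                f"but yield {len(seqs)} distinct mature sequences")
        members = sorted(members, key=lambda g: g.copy_index)
        families.append(TRNAFamily(
            name=f"{w}-{x}-{y}-{len(members)}",
            kind="mature",
            sequence=members[0].mature_sequence(),
            member_gene_ids=tuple(g.gene_id for g in members),
            body_start=1,
            body_end=len(members[0].mature_sequence()),
        ))
    by_seq: dict[str, list[str]] = defaultdict(list)
    for fam in families:
        by_seq[fam.sequence].append(fam.name)
    for seq, names in by_seq.items():
        if len(names) > 1:
            log.warning("identical mature sequence under distinct family metadata "
                        "(not merged): %s", ", ".join(names))
    return families


def build_pre_library(genes: Sequence[TRNAGene]) -> list[TRNAFamily]:
    """Aggregate genes of one W-X-Y mature family with identical pre-tRNA
    (flank + unspliced body + flank) sequence into families named
    ``pre-W-X-Y-Z.n`` (Z = largest member copy index, n = member count)."""
    _check_copy_indices(genes)
    families: list[TRNAFamily] = []
    for (w, x, y), members in sorted(_group_by_wxy(genes).items()):
        by_pre: dict[str, list[TRNAGene]] = defaultdict(list)
        for g in members:
            by_pre[g.pre_sequence()].append(g)
        for seq, group in sorted(by_pre.items(), key=lambda kv: max(g.copy_index for g in kv[1])):
            group = sorted(group, key=lambda g: g.copy_index)
            z = max(g.copy_index for g in group)
            families.append(TRNAFamily(
                name=f"pre-{w}-{x}-{y}-{z}.{len(group)}",
                kind="pre",
                sequence=seq,
                member_gene_ids=tuple(g.gene_id for g in group),
                body_start=FLANK_LENGTH + 1,
                body_end=len(seq) - FLANK_LENGTH,
            ))
    return families


def _mode_smallest(values: Iterable[int], label: str) -> int:
    counts = Counter(values)
    if not counts:
        raise ValueError(f"no values supplied for {label}")
    top = max(counts.values())
    modes = sorted(v for v, c in counts.items() if c == top)
    if len(modes) > 1:
        log.warning("multimodal %s positions %s; using smallest (%d)", label, modes, modes[0])
    return modes[0]


def generalized_loop_bounds(structures: Sequence[LoopBounds] | None) -> LoopBounds:
    """Generalized loop coordinates: the per-field statistical mode across all
    annotated tRNAs.  With no annotations, the canonical defaults are used
    (D 13-22, anticodon 31-39, T -23..-15).  Multimodal ties resolve to the
    smallest candidate (warned), which widens rather than narrows the window.
    """
    if not structures:
        return DEFAULT_LOOP_BOUNDS
    return LoopBounds(
        d_start=_mode_smallest((s.d_start for s in structures), "D-loop start"),
        d_end=_mode_smallest((s.d_end for s in structures), "D-loop end"),
        a_start=_mode_smallest((s.a_start for s in structures), "anticodon-loop start"),
        a_end=_mode_smallest((s.a_end for s in structures), "anticodon-loop end"),
        t_start=_mode_smallest((s.t_start for s in structures), "T-loop start"),
        t_end=_mode_smallest((s.t_end for s in structures), "T-loop end"),
    )


# ---------------------------------------------------------------------------
# File interfaces: gene body FASTA + sidecar TSV, library FASTA, loops TSV.

def _format_introns(intervals: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in intervals)


def _parse_introns(text: str) -> list[tuple[int, int]]:
    text = (text or "").strip()
    if not text:
        return []
    out = []
    for part in text.split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return out


def write_genes(genes: Sequence[TRNAGene], bodies_fasta: str | Path, table_tsv: str | Path) -> None:
    """Write gene bodies as multi-FASTA (headers = gene_id) plus the metadata
    sidecar TSV this package defines as its rebuildable reference format."""
    records = [SeqRecord(Seq(g.body_sequence), id=g.gene_id, description="") for g in genes]
    SeqIO.write(records, str(bodies_fasta), "fasta")
    pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "amino_acid": [g.amino_acid for g in genes],
        "anticodon": [g.anticodon for g in genes],
        "family_index": [g.family_index for g in genes],
        "copy_index": [g.copy_index for g in genes],
        "introns": [_format_introns(g.intron_intervals) for g in genes],
        "flank5": [g.flank5 for g in genes],
        "flank3": [g.flank3 for g in genes],
    }).to_csv(table_tsv, sep="\t", index=False)


def read_genes(bodies_fasta: str | Path, table_tsv: str | Path,
               loops_tsv: str | Path | None = None) -> list[TRNAGene]:
    """Load genes from the body FASTA + sidecar TSV (and optional per-gene
    loop-annotation TSV)."""
    bodies = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(bodies_fasta), "fasta")}
    table = pd.read_csv(table_tsv, sep="\t", dtype={"introns": str}, keep_default_na=False)
    loops: dict[str, LoopBounds] = {}
    if loops_tsv is not None:
        ldf = pd.read_csv(loops_tsv, sep="\t")
        for row in ldf.itertuples():
            loops[row.gene_id] = LoopBounds(row.d_start, row.d_end, row.a_start,
                                            row.a_end, row.t_start, row.t_end)
    genes = []
    for row in table.itertuples():
        if row.gene_id not in bodies:
            raise ValueError(f"gene {row.gene_id} in table but absent from FASTA")
        genes.append(TRNAGene(
            gene_id=row.gene_id,
            amino_acid=row.amino_acid,
            anticodon=row.anticodon,
            family_index=int(row.family_index),
            copy_index=int(row.copy_index),
            body_sequence=bodies[row.gene_id],
            intron_intervals=_parse_introns(row.introns),
            flank5=row.flank5,
            flank3=row.flank3,
            loop_bounds=loops.get(row.gene_id),
        ))
    return genes


def write_library(families: Sequence[TRNAFamily], fasta_path: str | Path,
                  members_tsv: str | Path | None = None) -> None:
    records = [SeqRecord(Seq(f.sequence), id=f.name, description="") for f in families]
    SeqIO.write(records, str(fasta_path), "fasta")
    if members_tsv is not None:
        pd.DataFrame({
            "family": [f.name for f in families],
            "kind": [f.kind for f in families],
            "member_gene_ids": [",".join(f.member_gene_ids) for f in families],
        }).to_csv(members_tsv, sep="\t", index=False)


def load_library(fasta_path: str | Path, kind: str) -> list[TRNAFamily]:
    """Load a previously written library FASTA; body bounds are recomputed
    from the kind (mature: whole sequence, pre: inside the 40-nt flanks)."""
    families = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if kind == "mature":
            start, end = 1, len(seq)
        else:
            start, end = FLANK_LENGTH + 1, len(seq) - FLANK_LENGTH
        families.append(TRNAFamily(rec.id, kind, seq, (), start, end))
    return families
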