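"""Synthetic reference and read generation with ground-truth tables.

The simulator builds a small, fully controlled stand-in for a real tRNA gene
annotation plus a small RNA-seq library: random gene bodies with 40-nt
flanks (and optional introns), and reads emitted from declared tDR spans
with declared error patterns (a substituted base, or one/two/three reference
bases skipped — mirroring the mismatch and deletion signatures of chemical
modifications).  Because every read is declared, the expected alignment
stage, primary tDR name and relative abundance of every family are known
exactly and written to truth tables, enabling end-to-end parameter-recovery
tests of the whole pipeline.

Defaults emulate the human scale: 73-nt gene bodies (76-nt mature sequence
with the CCA), declared read counts at or above the 100-copy abundance
floor, and uniform Q41 base qualities (error types are injected explicitly,
never via sequencing noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import naming, reference
from .align import ErrorType, Placement
from .preprocess import UniqueRead
from .reference import TRNAGene, TRNAFamily, build_mature_library, build_pre_library

_BASES = "ACGT"

_ERROR_STAGES = {
    ("mature", "none"): ErrorType.EXACT_MATURE,
    ("pre", "none"): ErrorType.EXACT_PRE,
    ("mature", "mm1"): ErrorType.MM1,
    ("mature", "del1"): ErrorType.DEL1,
    ("mature", "mm2"): ErrorType.MM2,
    ("mature", "del2"): ErrorType.DEL2,
    ("mature", "del3"): ErrorType.DEL3,
}

# reference offsets touched by each error pattern, relative to the first
# error position (del2 leaves an intact base between its two deletions so it
# is never claimed by the contiguous three-base stage)
_ERROR_OFFSETS = {
    "mm1": (0,), "del1": (0,), "mm2": (0, 3), "del2": (0, 2), "del3": (0, 1, 2),
}
_EDGE_MARGIN = 2  # error positions keep this many intact bases from span ends


@dataclass
class TDRDecl:
    """One declared tDR: a span on its family's reference sequence, a copy
    count and an optional error pattern anchored at ``error_pos``."""

    region: str  # "mature" | "pre"
    span: tuple[int, int]
    count: int
    error: str = "none"
    error_pos: int | None = None

    def __post_init__(self) -> None:
        if self.region not in ("mature", "pre"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.error not in ("none",) and self.error not in _ERROR_OFFSETS:
            raise ValueError(f"unknown error pattern {self.error!r}")
        if self.region == "pre" and self.error != "none":
            raise ValueError("pre-tRNA reads are exact-only; error patterns apply to mature reads")
        if self.error != "none" and self.error_pos is None:
            raise ValueError(f"error pattern {self.error!r} requires error_pos")
        self.span = (int(self.span[0]), int(self.span[1]))


@dataclass
class FamilySpec:
    amino_acid: str
    anticodon: str
    family_index: int = 1
    multiplicity: int = 1
    body_length: int = 73
    intron: tuple[int, int] | None = None
    tdrs: list[TDRDecl] = field(default_factory=list)

    @property
    def mature_name(self) -> str:
        return f"{self.amino_acid}-{self.anticodon}-{self.family_index}-{self.multiplicity}"

    @property
    def pre_name(self) -> str:
        return (f"pre-{self.amino_acid}-{self.anticodon}-{self.family_index}-"
                f"{self.multiplicity}.{self.multiplicity}")


@dataclass
class SimSpec:
    families: list[FamilySpec]
    seed: int = 0
    noise_reads: int = 0
    quality_char: str = "J"  # Q41


@dataclass
class SimulatedSample:
    genes: list[TRNAGene]
    mature_lib: list[TRNAFamily]
    pre_lib: list[TRNAFamily]
    reads: list[tuple[str, int, str, str]]  # sequence, count, family, stage name
    truth_reads: pd.DataFrame
    truth_families: pd.DataFrame


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def make_reference(spec: SimSpec, rng: np.random.Generator | None = None,
                   out_dir: str | Path | None = None) -> list[TRNAGene]:
    """Generate annotated genes for every family spec (``multiplicity``
    identical copies each); mature sequences are guaranteed pairwise
    distinct across family specs.  Optionally writes ``bodies.fa`` and
    ``genes.tsv`` under ``out_dir``."""
    rng = rng or np.random.default_rng(spec.seed)
    genes: list[TRNAGene] = []
    seen_mature: set[str] = set()
    for fam in spec.families:
        if fam.intron is not None:
            s, e = fam.intron
            if not (1 <= s <= e <= fam.body_length):
                raise ValueError(f"{fam.mature_name}: intron {fam.intron} outside body")
        for _attempt in range(100):
            body = _random_seq(rng, fam.body_length)
            flank5 = _random_seq(rng, reference.FLANK_LENGTH)
            flank3 = _random_seq(rng, reference.FLANK_LENGTH)
            probe = TRNAGene(
                gene_id=f"{fam.amino_acid}-{fam.anticodon}-{fam.family_index}-probe",
                amino_acid=fam.amino_acid, anticodon=fam.anticodon,
                family_index=fam.family_index, copy_index=1,
                body_sequence=body,
                intron_intervals=[fam.intron] if fam.intron else [],
                flank5=flank5, flank3=flank3)
            if probe.mature_sequence() not in seen_mature:
                break
        else:
            raise RuntimeError("could not draw a distinct mature sequence")
        seen_mature.add(probe.mature_sequence())
        for copy in range(1, fam.multiplicity + 1):
            genes.append(TRNAGene(
                gene_id=f"{fam.amino_acid}-{fam.anticodon}-{fam.family_index}-{copy}",
                amino_acid=fam.amino_acid, anticodon=fam.anticodon,
                family_index=fam.family_index, copy_index=copy,
                body_sequence=body,
                intron_intervals=[fam.intron] if fam.intron else [],
                flank5=flank5, flank3=flank3))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        reference.write_genes(genes, out_dir / "bodies.fa", out_dir / "genes.tsv")
    return genes


def _make_read(ref_seq: str, decl: TDRDecl, family_name: str) -> str:
    """Build the read sequence a declared tDR emits: the declared span with
    its error pattern applied (base substituted or reference bases skipped)."""
    start, end = decl.span
    if not (1 <= start <= end <= len(ref_seq)):
        raise ValueError(f"{family_name}: span {decl.span} outside reference "
                         f"of length {len(ref_seq)}")
    segment = ref_seq[start - 1 : end]
    if decl.error == "none":
        return segment
    offsets = [decl.error_pos - start + off for off in _ERROR_OFFSETS[decl.error]]
    if offsets[0] < _EDGE_MARGIN or offsets[-1] > len(segment) - 1 - _EDGE_MARGIN:
        raise ValueError(
            f"{family_name}: error pattern {decl.error} at {decl.error_pos} too close "
            f"to the span edge (needs {_EDGE_MARGIN} intact bases on each side)")
    if decl.error.startswith("mm"):
        chars = list(segment)
        for off in offsets:
            chars[off] = _BASES[(_BASES.index(chars[off]) + 1) % 4]
        return "".join(chars)
    return "".join(ch for i, ch in enumerate(segment) if i not in set(offsets))


def simulate_reads(genes: Sequence[TRNAGene], spec: SimSpec,
                   out_dir: str | Path | None = None,
                   rng: np.random.Generator | None = None) -> SimulatedSample:
    """Emit the declared reads (plus singleton noise reads) and the truth
    tables; optionally writes ``reads.fastq``, ``truth_reads.tsv`` and
    ``truth_families.tsv`` under ``out_dir``."""
    rng = rng or np.random.default_rng(spec.seed + 1)
    mature_lib = build_mature_library(genes)
    pre_lib = build_pre_library(genes)
    by_name = {f.name: f for f in mature_lib + pre_lib}
    reads: list[tuple[str, int, str, str]] = []
    fam_decls: dict[str, list[tuple[TDRDecl, str]]] = {}
    for fam in spec.families:
        for decl in fam.tdrs:
            name = fam.mature_name if decl.region == "mature" else fam.pre_name
            family = by_name[name]
            seq = _make_read(family.sequence, decl, name)
            if not 14 <= len(seq) <= 40:
                raise ValueError(f"{name}: declared read length {len(seq)} outside 14..40")
            stage = _ERROR_STAGES[(decl.region, decl.error)]
            reads.append((seq, decl.count, name, stage.name))
            fam_decls.setdefault(name, []).append((decl, seq))
    truth_reads = pd.DataFrame(reads, columns=["sequence", "count", "family", "stage"])

    total_mapped = int(truth_reads["count"].sum()) if len(truth_reads) else 0
    fam_rows = []
    for name, decls in fam_decls.items():
        family = by_name[name]
        placed = []
        for decl, seq in decls:
            start, end = decl.span
            stage = _ERROR_STAGES[(decl.region, decl.error)]
            placed.append((UniqueRead(seq, decl.count), stage,
                           Placement(name, start, end - start + 1)))
        profile = naming.compute_coverage(family, placed)
        primary = naming.name_primary(family, profile)
        count = sum(d.count for d, _ in decls)
        fam_rows.append({
            "family": name, "kind": family.kind, "read_count": count,
            "max_coverage": profile.max_coverage,
            "relative_abundance": (count / total_mapped) * profile.max_coverage * 100.0,
            "primary_name": primary.full_name,
        })
    truth_families = pd.DataFrame(
        fam_rows, columns=["family", "kind", "read_count", "max_coverage",
                           "relative_abundance", "primary_name"])

    noise = [( _random_seq(rng, int(rng.integers(14, 41))), 1, "", "NOISE")
             for _ in range(spec.noise_reads)]

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "reads.fastq", "w") as fh:
            idx = 0
            for seq, count, _fam, _stage in reads + noise:
                for _ in range(count):
                    idx += 1
                    fh.write(f"@sim_{idx}\n{seq}\n+\n{spec.quality_char * len(seq)}\n")
        truth_reads.to_csv(out_dir / "truth_reads.tsv", sep="\t", index=False)
        truth_families.to_csv(out_dir / "truth_families.tsv", sep="\t", index=False)
        reference.write_library(mature_lib, out_dir / "mature.fa")
        reference.write_library(pre_lib, out_dir / "pre.fa")
    return SimulatedSample(list(genes), mature_lib, pre_lib, reads + noise,
                           truth_reads, truth_families)


def simulate(spec: SimSpec, out_dir: str | Path | None = None) -> SimulatedSample:
    """Convenience wrapper: reference + reads + truth in one call."""
    rng = np.random.default_rng(spec.seed)
    genes = make_reference(spec, rng=rng, out_dir=out_dir)
    return simulate_reads(genes, spec, out_dir=out_dir, rng=rng)


def load_sim_spec(path: str | Path) -> SimSpec:
    """Read a simulation spec from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    families = []
    for f in raw.get("families", []):
        tdrs = [TDRDecl(region=t.get("region", "mature"),
                        span=tuple(t["span"]),
                        count=int(t["count"]),
                        error=t.get("error", "none"),
                        error_pos=t.get("error_pos"))
                for t in f.get("tdrs", [])]
        families.append(FamilySpec(
            amino_acid=f["amino_acid"], anticodon=f["anticodon"],
            family_index=int(f.get("family_index", 1)),
            multiplicity=int(f.get("multiplicity", 1)),
            body_length=int(f.get("body_length", 73)),
            intron=tuple(f["intron"]) if f.get("intron") else None,
            tdrs=tdrs))
    return SimSpec(families=families, seed=int(raw.get("seed", 0)),
                   noise_reads=int(raw.get("noise_reads", 0)))
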