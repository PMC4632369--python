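"""Quantification of tDRs: relative abundance, error-type proportions,
per-sample reports and post-hoc aggregation.

The central quantity is the relative abundance of a family's primary tDR:

    relative_abundance = (reads mapped to the family
                          / reads mapped to all tRNAs)
                         * highest coverage proportion * 100

Multi-mapping is handled by full counting: every time a read places in a
family it contributes its entire copy count to that family (no fractional
splitting), while the denominator counts each mapped read once.  Multiplying
by the maximum coverage proportion restricts the estimate to reads spanning
the best-covered position — a ceiling on the fraction of reads belonging to
the primary tDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .align import AlignmentAssignment, ErrorType
from .naming import CoverageProfile, PrimaryTDR

REPORT_COLUMNS = ["family", "kind", "read_count", "max_coverage",
                  "relative_abundance", "primary_length", "size_class",
                  "primary_name"]


@dataclass(frozen=True)
class FamilyReport:
    family_name: str
    kind: str
    read_count: int
    max_coverage: float
    relative_abundance: float
    primary: PrimaryTDR
    stage_proportions: dict[ErrorType, float]


def relative_abundance(family_reads: int, total_mapped: int, max_coverage: float) -> float:
    """The primary-tDR relative abundance, as a percentage (full precision;
    report tables round to one decimal)."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    if not 0.0 <= max_coverage <= 1.0:
        raise ValueError("max_coverage must lie in [0, 1]")
    return (family_reads / total_mapped) * max_coverage * 100.0


def count_family_reads(assignments: Sequence[AlignmentAssignment],
                       ) -> tuple[dict[str, int], int]:
    """Per-family read counts and the shared denominator.

    A read placed in k families contributes its full count to each of the k
    families but only once to ``total_mapped``.
    """
    per_family: dict[str, int] = {}
    total_mapped = 0
    for a in assignments:
        total_mapped += a.read.count
        for p in a.placements:
            per_family[p.family_name] = per_family.get(p.family_name, 0) + a.read.count
    return per_family, total_mapped


def stage_proportions(assignments: Sequence[AlignmentAssignment],
                      grouping: str = "all",
                      ) -> dict[ErrorType, float] | dict[str, dict[ErrorType, float]]:
    """Fraction of mapped read counts at each hierarchy stage.

    ``grouping="all"`` pools every mapped read (counted once); ``"per-family"``
    computes the proportions within each family's placed reads.
    """
    if grouping == "all":
        totals: dict[ErrorType, int] = {}
        for a in assignments:
            totals[a.stage] = totals.get(a.stage, 0) + a.read.count
        grand = sum(totals.values())
        return {stage: c / grand for stage, c in totals.items()} if grand else {}
    if grouping == "per-family":
        fam_totals: dict[str, dict[ErrorType, int]] = {}
        for a in assignments:
            for p in a.placements:
                d = fam_totals.setdefault(p.family_name, {})
                d[a.stage] = d.get(a.stage, 0) + a.read.count
        out: dict[str, dict[ErrorType, float]] = {}
        for fam, d in fam_totals.items():
            grand = sum(d.values())
            out[fam] = {stage: c / grand for stage, c in d.items()}
        return out
    raise ValueError(f"unknown grouping {grouping!r}")


def build_report(assignments: Sequence[AlignmentAssignment],
                 profiles: Mapping[str, CoverageProfile],
                 primaries: Mapping[str, PrimaryTDR],
                 ) -> tuple[list[FamilyReport], int]:
    """Assemble per-family reports, sorted by descending relative abundance
    (ties by family name).  Returns (reports, total_mapped)."""
    per_family, total_mapped = count_family_reads(assignments)
    per_family_stages = stage_proportions(assignments, "per-family")
    reports = []
    for fam, count in per_family.items():
        profile = profiles[fam]
        reports.append(FamilyReport(
            family_name=fam,
            kind=profile.kind,
            read_count=count,
            max_coverage=profile.max_coverage,
            relative_abundance=relative_abundance(count, total_mapped, profile.max_coverage),
            primary=primaries[fam],
            stage_proportions=per_family_stages[fam],
        ))
    reports.sort(key=lambda r: (-r.relative_abundance, r.family_name))
    return reports, total_mapped


def report_frame(reports: Sequence[FamilyReport]) -> pd.DataFrame:
    """Tabular view of the reports; relative abundance keeps full precision
    (tables written to disk round to one decimal)."""
    rows = []
    for r in reports:
        row = {
            "family": r.family_name,
            "kind": r.kind,
            "read_count": r.read_count,
            "max_coverage": r.max_coverage,
            "relative_abundance": r.relative_abundance,
            "primary_length": r.primary.primary_length,
            "size_class": r.primary.size_class,
            "primary_name": r.primary.full_name,
        }
        for stage in ErrorType:
            row[f"prop_{stage.name}"] = r.stage_proportions.get(stage, 0.0)
        rows.append(row)
    columns = REPORT_COLUMNS + [f"prop_{s.name}" for s in ErrorType]
    return pd.DataFrame(rows, columns=columns)


def parse_family_name(name: str) -> dict[str, str | bool]:
    """Split a family name into its components.

    Handles the optional ``pre-`` prefix, the pre-family ``.n`` suffix, and
    amino-acid labels that themselves contain dashes (``nmt-tRNA-...``): the
    last three dash-separated tokens are anticodon, family identifier and
    copy count; everything before them is the amino-acid label.
    """
    is_pre = name.startswith("pre-")
    core = name[4:] if is_pre else name
    if is_pre:
        core = core.rsplit(".", 1)[0]
    parts = core.rsplit("-", 3)
    if len(parts) != 4:
        raise ValueError(f"unparseable family name {name!r}")
    w, x, y, z = parts
    return {"amino_acid": w, "anticodon": x, "family_index": y, "copies": z, "pre": is_pre}


def aggregate(report: pd.DataFrame, level: str, total_mapped: int) -> pd.DataFrame:
    """Post-hoc aggregation of the family report into isodecoder
    (``anticodon``) or amino-acid super-families.

    Read counts are summed within the grouping key (parsed from family
    names, pre families grouped under a ``pre-`` key of their own) and
    relative abundance is recomputed using the maximum of the member
    families' maximum coverages.
    """
    if level == "family":
        return report.copy()
    if level not in ("anticodon", "amino_acid"):
        raise ValueError(f"unknown aggregation level {level!r}")

    def key(name: str) -> str:
        p = parse_family_name(name)
        prefix = "pre-" if p["pre"] else ""
        if level == "anticodon":
            return f"{prefix}{p['amino_acid']}-{p['anticodon']}"
        return f"{prefix}{p['amino_acid']}"

    df = report.assign(group=report["family"].map(key))
    agg = df.groupby("group", sort=True).agg(
        read_count=("read_count", "sum"),
        max_coverage=("max_coverage", "max"),
        n_families=("family", "size"),
    ).reset_index()
    agg["relative_abundance"] = [
        relative_abundance(c, total_mapped, m)
        for c, m in zip(agg["read_count"], agg["max_coverage"])
    ]
    agg.sort_values(["relative_abundance", "group"], ascending=[False, True],
                    inplace=True, kind="mergesort")
    return agg.reset_index(drop=True)
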