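"""End-to-end pipeline: preprocess -> hierarchical alignment -> coverage and
naming -> quantification -> reports and coverage maps.

``run_pipeline`` is the library entry point behind the command line: it
consumes a FASTQ plus mature/pre reference libraries and produces per-family
report tables (one for mature, one for pre families, sharing a single
all-mapped-reads denominator), per-family coverage-profile tables, coverage
maps and a run summary whose read buckets are conserved:

    input = quality + length + count + mapped + unmapped
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import naming, quantify, viz
from .align import AlignmentResult, DEFAULT_STAGE_ORDER, ErrorType, group_by_family, run_hierarchy
from .naming import CoverageProfile, PrimaryTDR
from .preprocess import collapse_and_filter, read_fastq
from .quantify import FamilyReport
from .reference import DEFAULT_LOOP_BOUNDS, LoopBounds, TRNAFamily, load_library

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    summary: dict
    mature_report: pd.DataFrame
    pre_report: pd.DataFrame
    reports: list[FamilyReport]
    profiles: dict[str, CoverageProfile]
    primaries: dict[str, PrimaryTDR]
    alignment: AlignmentResult
    total_mapped: int
    output_files: list[Path] = field(default_factory=list)


def _as_library(lib, kind: str) -> list[TRNAFamily]:
    if isinstance(lib, (str, Path)):
        return load_library(lib, kind)
    return list(lib)


def run_pipeline(fastq: str | Path,
                 mature_lib,
                 pre_lib,
                 out_prefix: str | Path | None = None,
                 *,
                 loop_bounds: LoopBounds = DEFAULT_LOOP_BOUNDS,
                 min_q: int = 28,
                 min_len: int = 14,
                 max_len: int = 40,
                 min_count: int = 100,
                 min_count_frac: float | None = None,
                 stage_order: Sequence[ErrorType] = DEFAULT_STAGE_ORDER,
                 top_n: int = 50,
                 error_overlay_min: float = 0.05,
                 make_figures: bool = True,
                 figure_format: str = "svg",
                 dump_collapsed: bool = False,
                 dump_assignments: bool = False) -> PipelineResult:
    """Run the full pipeline; when ``out_prefix`` is given, report TSVs,
    profile TSVs, figures and a JSON run summary are written next to it.
    On failure any partially written outputs are removed."""
    written: list[Path] = []
    try:
        return _run(fastq, mature_lib, pre_lib, out_prefix, written,
                    loop_bounds=loop_bounds, min_q=min_q, min_len=min_len,
                    max_len=max_len, min_count=min_count,
                    min_count_frac=min_count_frac, stage_order=stage_order,
                    top_n=top_n, error_overlay_min=error_overlay_min,
                    make_figures=make_figures, figure_format=figure_format,
                    dump_collapsed=dump_collapsed, dump_assignments=dump_assignments)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run(fastq, mature_lib, pre_lib, out_prefix, written, *, loop_bounds,
         min_q, min_len, max_len, min_count, min_count_frac, stage_order,
         top_n, error_overlay_min, make_figures, figure_format,
         dump_collapsed, dump_assignments) -> PipelineResult:
    mature = _as_library(mature_lib, "mature")
    pre = _as_library(pre_lib, "pre")
    by_name = {f.name: f for f in mature + pre}

    uniques, stats = collapse_and_filter(
        read_fastq(fastq), min_q=min_q, min_len=min_len, max_len=max_len,
        min_count=min_count, min_count_frac=min_count_frac)
    log.info("preprocess: %d input reads -> %d unique sequences (%d raw reads)",
             stats.n_input, stats.n_unique, stats.n_surviving)

    result = run_hierarchy(uniques, mature, pre, stage_order)
    mapped_raw = sum(a.read.count for a in result.assignments)
    unmapped_raw = sum(u.count for u in result.unmapped)
    for stage in stage_order:
        n = sum(a.read.count for a in result.assignments if a.stage is stage)
        if n:
            log.info("stage %s: %d raw reads", stage.name, n)

    profiles: dict[str, CoverageProfile] = {}
    primaries: dict[str, PrimaryTDR] = {}
    for fam_name, placed in group_by_family(result.assignments).items():
        family = by_name[fam_name]
        profile = naming.compute_coverage(family, placed)
        profiles[fam_name] = profile
        primaries[fam_name] = naming.name_primary(family, profile, loop_bounds)

    reports, total_mapped = quantify.build_report(result.assignments, profiles, primaries)
    frame = quantify.report_frame(reports)
    mature_report = frame[frame["kind"] == "mature"].reset_index(drop=True)
    pre_report = frame[frame["kind"] == "pre"].reset_index(drop=True)

    summary = {
        "input_reads": stats.n_input,
        "discarded_quality": stats.n_fail_quality,
        "discarded_length": stats.n_fail_length,
        "discarded_count": stats.n_fail_count,
        "unique_reads": stats.n_unique,
        "mapped_reads": mapped_raw,
        "unmapped_reads": unmapped_raw,
        "total_mapped": total_mapped,
        "families_mature": int((frame["kind"] == "mature").sum()),
        "families_pre": int((frame["kind"] == "pre").sum()),
        "stage_counts": {s.name: sum(a.read.count for a in result.assignments
                                     if a.stage is s) for s in stage_order},
    }

    out = PipelineResult(summary, mature_report, pre_report, reports,
                         profiles, primaries, result, total_mapped, written)
    if out_prefix is not None:
        _write_outputs(out, by_name, Path(out_prefix), written, uniques,
                       top_n=top_n, error_overlay_min=error_overlay_min,
                       make_figures=make_figures, figure_format=figure_format,
                       dump_collapsed=dump_collapsed,
                       dump_assignments=dump_assignments)
    return out


def _round_report(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        return df
    df = df.copy()
    df["relative_abundance"] = df["relative_abundance"].round(1)
    return df


def _write_outputs(result: PipelineResult, by_name, prefix: Path,
                   written: list[Path], uniques, *, top_n, error_overlay_min,
                   make_figures, figure_format, dump_collapsed,
                   dump_assignments) -> None:
    prefix.parent.mkdir(parents=True, exist_ok=True)

    def register(path: Path) -> Path:
        written.append(path)
        return path

    _round_report(result.mature_report).to_csv(
        register(prefix.with_name(prefix.name + ".mature_report.tsv")), sep="\t", index=False)
    _round_report(result.pre_report).to_csv(
        register(prefix.with_name(prefix.name + ".pre_report.tsv")), sep="\t", index=False)

    profile_rows = []
    for fam_name, profile in result.profiles.items():
        seq = by_name[fam_name].sequence
        for i in range(profile.length):
            row = {"family": fam_name, "position": i + 1, "base": seq[i],
                   "coverage": float(profile.coverage[i])}
            for cls in naming.ERROR_CLASSES:
                row[cls] = float(profile.error_fractions[cls][i])
            profile_rows.append(row)
    pd.DataFrame(profile_rows).to_csv(
        register(prefix.with_name(prefix.name + ".profiles.tsv")), sep="\t", index=False)

    with open(register(prefix.with_name(prefix.name + ".summary.json")), "w") as fh:
        json.dump(result.summary, fh, indent=2)

    if dump_collapsed:
        from .preprocess import write_collapsed
        write_collapsed(uniques, register(prefix.with_name(prefix.name + ".collapsed.tsv")))
    if dump_assignments:
        from .align import dump_assignments as _dump
        _dump(result.alignment, register(prefix.with_name(prefix.name + ".assignments.tsv")))

    if make_figures:
        spec = viz.MapSpec(top_n=top_n, error_overlay_min=error_overlay_min,
                           fmt=figure_format)
        sequences = {name: fam.sequence for name, fam in by_name.items()}
        path = viz.mature_coverage_map(
            result.mature_report, result.profiles, sequences, spec,
            prefix.with_name(prefix.name + f".mature_map.{figure_format}"))
        if path is not None:
            register(path)
        path = viz.pre_coverage_map(
            result.pre_report, result.profiles, spec,
            prefix.with_name(prefix.name + f".pre_map.{figure_format}"))
        if path is not None:
            register(path)
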