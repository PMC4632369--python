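"""Coverage-map figures: one dot-matrix row per tRNA family.

Each row of a coverage map is one family (top N by relative abundance,
descending); each dot is one reference position, sized linearly by the
fraction of the family's reads covering it.  Mature maps colour dots by
nucleotide and overlay a marker wherever an error class (mismatch,
single-base deletion, three-base deletion) exceeds the overlay threshold at
that position — when two classes both qualify, only the more frequent one is
drawn.  Pre maps colour dots by region (leader / body / trailer) and carry
no error overlays, since pre-tRNA alignment is exact-only.

The style (colours, markers, dot scale) lives in :class:`MapSpec`, not in the
drawing code; rendering is deterministic, so identical inputs give
byte-identical SVG output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

import pandas as pd  # noqa: E402

from .naming import ERROR_CLASSES, CoverageProfile  # noqa: E402

log = logging.getLogger(__name__)

# stable SVG ids across runs
matplotlib.rcParams["svg.hashsalt"] = "tdrkit"


@dataclass
class MapSpec:
    """Rendering parameters and style table for coverage maps."""

    top_n: int = 50
    error_overlay_min: float = 0.05
    fmt: str = "svg"
    dot_scale: float = 55.0  # marker area at coverage 1.0 (pt^2), linear in coverage
    min_draw_coverage: float = 0.01
    nucleotide_colors: dict[str, str] = field(default_factory=lambda: {
        "A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "T": "#e31a1c", "N": "#999999"})
    region_colors: dict[str, str] = field(default_factory=lambda: {
        "leader": "#d62728", "body": "#ff7f0e", "trailer": "#ffd92f"})
    error_markers: dict[str, str] = field(default_factory=lambda: {
        "mismatch": "^", "del1": "s", "del3": "D"})

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be at least 1")
        if not 0.0 <= self.error_overlay_min <= 1.0:
            raise ValueError("error_overlay_min must lie in [0, 1]")


def select_top(report: pd.DataFrame, spec: MapSpec) -> pd.DataFrame:
    """The rows to draw: top ``spec.top_n`` by relative abundance (the report
    is already sorted descending)."""
    return report.head(spec.top_n)


def overlay_points(profile: CoverageProfile, spec: MapSpec) -> list[tuple[int, str, float]]:
    """(position, error class, fraction) triples to overlay: positions where
    an error-class fraction exceeds the threshold, keeping only the most
    frequent class per position."""
    points = []
    for i in range(profile.length):
        candidates = [(float(profile.error_fractions[cls][i]), cls) for cls in ERROR_CLASSES]
        candidates = [(f, c) for f, c in candidates if f > spec.error_overlay_min]
        if candidates:
            # most frequent class wins; ties resolve to the earlier class
            frac, cls = max(candidates, key=lambda fc: fc[0])
            points.append((i + 1, cls, frac))
    return points


def region_of(profile: CoverageProfile, position: int) -> str:
    """leader / body / trailer classification of a 1-based pre-tRNA position."""
    if position < profile.body_start:
        return "leader"
    if position > profile.body_end:
        return "trailer"
    return "body"


def _new_figure(n_rows: int, max_len: int):
    width = max(6.0, min(16.0, max_len * 0.12))
    height = max(2.0, 0.32 * n_rows + 1.2)
    fig, ax = plt.subplots(figsize=(width, height))
    ax.set_xlim(0, max_len + 1)
    ax.set_ylim(-0.5, n_rows - 0.5)
    ax.set_xlabel("position in tRNA")
    ax.invert_yaxis()  # most abundant family on top
    return fig, ax


def _save(fig, out_path: Path) -> None:
    fig.savefig(out_path, format=out_path.suffix.lstrip("."), metadata={"Date": None})
    plt.close(fig)


def mature_coverage_map(report: pd.DataFrame,
                        profiles: Mapping[str, CoverageProfile],
                        sequences: Mapping[str, str],
                        spec: MapSpec,
                        out_path: str | Path) -> Path | None:
    """Render the mature-family coverage map; returns the file path, or None
    (with a warning) when the report is empty."""
    rows = select_top(report, spec)
    if rows.empty:
        log.warning("no mature families to draw; skipping coverage map")
        return None
    out_path = Path(out_path)
    max_len = max(profiles[f].length for f in rows["family"])
    fig, ax = _new_figure(len(rows), max_len)
    labels = []
    for y, row in enumerate(rows.itertuples()):
        profile = profiles[row.family]
        seq = sequences[row.family]
        labels.append(f"{row.family} ({row.relative_abundance:.1f}%)")
        for i in range(profile.length):
            cov = float(profile.coverage[i])
            if cov < spec.min_draw_coverage:
                continue
            ax.scatter(i + 1, y, s=cov * spec.dot_scale,
                       color=spec.nucleotide_colors.get(seq[i], "#999999"),
                       linewidths=0, zorder=2)
        for pos, cls, frac in overlay_points(profile, spec):
            ax.scatter(pos, y, s=frac * spec.dot_scale * 1.6,
                       marker=spec.error_markers[cls], facecolors="none",
                       edgecolors="black", linewidths=0.6, zorder=3)
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_title("Mature tRNA coverage map")
    fig.tight_layout()
    _save(fig, out_path)
    return out_path


def pre_coverage_map(report: pd.DataFrame,
                     profiles: Mapping[str, CoverageProfile],
                     spec: MapSpec,
                     out_path: str | Path) -> Path | None:
    """Render the pre-family coverage map (dots coloured by leader / body /
    trailer region, no error overlays)."""
    rows = select_top(report, spec)
    if rows.empty:
        log.warning("no pre families to draw; skipping coverage map")
        return None
    out_path = Path(out_path)
    max_len = max(profiles[f].length for f in rows["family"])
    fig, ax = _new_figure(len(rows), max_len)
    labels = []
    for y, row in enumerate(rows.itertuples()):
        profile = profiles[row.family]
        labels.append(f"{row.family} ({row.relative_abundance:.1f}%)")
        for i in range(profile.length):
            cov = float(profile.coverage[i])
            if cov < spec.min_draw_coverage:
                continue
            ax.scatter(i + 1, y, s=cov * spec.dot_scale,
                       color=spec.region_colors[region_of(profile, i + 1)],
                       linewidths=0, zorder=2)
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_title("Pre-tRNA coverage map")
    fig.tight_layout()
    _save(fig, out_path)
    return out_path
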