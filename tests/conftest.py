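import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tdrkit.naming import CoverageProfile, ERROR_CLASSES
from tdrkit.reference import TRNAFamily

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_mature_family(sequence: str, name: str = "Gly-GCC-1-1") -> TRNAFamily:
    """A mature family from an explicit sequence (must end in CCA)."""
    return TRNAFamily(name, "mature", sequence, (), 1, len(sequence))


def make_pre_family(sequence: str, name: str = "pre-Gly-GCC-1-1.1") -> TRNAFamily:
    """A pre family from an explicit sequence (length > 80: 40-nt flanks)."""
    return TRNAFamily(name, "pre", sequence, (), 41, len(sequence) - 40)


def make_profile(length: int, segments: dict[tuple[int, int], float],
                 kind: str = "mature", name: str = "Gly-GCC-1-1",
                 body_start: int | None = None, body_end: int | None = None,
                 errors: dict[str, dict[int, float]] | None = None) -> CoverageProfile:
    """Hand-constructed coverage profile: ``segments`` maps 1-based closed
    spans to coverage fractions (later spans overwrite earlier ones)."""
    coverage = np.zeros(length)
    for (start, end), frac in segments.items():
        coverage[start - 1 : end] = frac
    fracs = {cls: np.zeros(length) for cls in ERROR_CLASSES}
    for cls, by_pos in (errors or {}).items():
        for pos, frac in by_pos.items():
            fracs[cls][pos - 1] = frac
    if body_start is None:
        body_start = 1 if kind == "mature" else 41
    if body_end is None:
        body_end = length if kind == "mature" else length - 40
    return CoverageProfile(name, kind, length, coverage, fracs,
                           total_count=1000, body_start=body_start, body_end=body_end)


def write_fastq(path, reads: list[tuple[str, str, int]]) -> int:
    """Write (sequence, quality, copies) triples as FASTQ; returns the total
    number of records written."""
    n = 0
    with open(path, "w") as fh:
        for seq, qual, copies in reads:
            for _ in range(copies):
                n += 1
                fh.write(f"@r{n}\n{seq}\n+\n{qual}\n")
    return n


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)
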