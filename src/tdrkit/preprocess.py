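"""FASTQ preprocessing: quality filtering, length filtering, read collapsing.

The mapper works on *unique* read sequences with copy counts rather than on
individual reads: modification-induced mismatch/deletion calls are only
trusted when every base call is confident and a sequence is abundant enough
to be signal rather than degradation noise.  The filters are, in order:

1. discard a read if any Phred+33 score is below ``min_q`` (default 28); a
   read containing an ambiguous ``N`` call is discarded at this step too,
   since it can never contribute a confident exact match;
2. discard reads shorter than ``min_len`` (14) or longer than ``max_len``
   (40) — short reads map everywhere by chance once mismatches and deletions
   are allowed;
3. collapse survivors by exact sequence and discard sequences observed fewer
   than ``min_count`` (100) times (inclusive threshold).  ``min_count_frac``
   expresses the threshold as a fraction of total input reads instead, for
   libraries of very different depth.
"""

from __future__ import annotations

import gzip
import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

PHRED_OFFSET = 33


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ records (e.g. quality characters below '!')."""


@dataclass(frozen=True)
class RawRead:
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FastqFormatError(
                f"sequence/quality length mismatch ({len(self.sequence)} vs {len(self.quality)})")


@dataclass(frozen=True)
class UniqueRead:
    """A collapsed read sequence and the number of surviving copies."""

    sequence: str
    count: int


@dataclass
class PreprocessStats:
    """Read-conservation ledger: every input read lands in exactly one bucket
    (quality, length, count) or survives into the unique-read set."""

    n_input: int = 0
    n_fail_quality: int = 0
    n_ambiguous: int = 0  # N-containing subset of n_fail_quality
    n_fail_length: int = 0
    n_fail_count: int = 0
    n_surviving: int = 0
    n_unique: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def passes_quality(read: RawRead, min_q: int = 28) -> bool:
    """True iff every position's Phred+33 score is at least ``min_q``
    (a score exactly at the threshold passes: the filter drops reads whose
    quality falls *below* it)."""
    floor = chr(PHRED_OFFSET + min_q)
    for ch in read.quality:
        if ch < "!":
            raise FastqFormatError(f"quality character {ch!r} below '!' is not valid Phred+33")
        if ch < floor:
            return False
    return True


def collapse_and_filter(reads: Iterable[RawRead], min_q: int = 28,
                        min_len: int = 14, max_len: int = 40,
                        min_count: int = 100,
                        min_count_frac: float | None = None,
                        ) -> tuple[list[UniqueRead], PreprocessStats]:
    """Apply the three filters and collapse to unique sequences.

    Returns the surviving unique reads sorted by descending count (ties by
    sequence) together with the conservation ledger.  Quality is applied
    before collapsing, so a unique sequence's count reflects only
    quality-passing copies.
    """
    stats = PreprocessStats()
    counter: Counter[str] = Counter()
    for read in reads:
        stats.n_input += 1
        if "N" in read.sequence:
            stats.n_fail_quality += 1
            stats.n_ambiguous += 1
            continue
        if not passes_quality(read, min_q):
            stats.n_fail_quality += 1
            continue
        if not (min_len <= len(read.sequence) <= max_len):
            stats.n_fail_length += 1
            continue
        counter[read.sequence] += 1
    if stats.n_input == 0:
        log.warning("empty input: no reads to collapse")
    if stats.n_ambiguous:
        log.info("discarded %d reads containing N calls", stats.n_ambiguous)
    threshold = min_count
    if min_count_frac is not None:
        threshold = max(1, math.ceil(min_count_frac * stats.n_input))
        log.info("abundance threshold: %.4g of %d input reads = %d copies",
                 min_count_frac, stats.n_input, threshold)
    uniques = []
    for seq, count in counter.items():
        if count >= threshold:
            uniques.append(UniqueRead(seq, count))
        else:
            stats.n_fail_count += count
    uniques.sort(key=lambda u: (-u.count, u.sequence))
    stats.n_surviving = sum(u.count for u in uniques)
    stats.n_unique = len(uniques)
    return uniques, stats


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream Phred+33 FASTQ records (optionally gzip-compressed)."""
    with _open_text(path) as handle:
        for _title, seq, qual in FastqGeneralIterator(handle):
            yield RawRead(seq.upper(), qual)


def write_collapsed(uniques: list[UniqueRead], path: str | Path) -> None:
    """Dump collapsed reads as a two-column TSV (sequence, count)."""
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for u in uniques:
            fh.write(f"{u.sequence}\t{u.count}\n")
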