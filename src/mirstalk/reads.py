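"""Small-RNA read processing: adapter trimming, cleaning filters, collapsing.

The cleaning rules mirror standard plant sRNA-seq practice: keep 10-30 nt
inserts, drop reads carrying a 5' adapter contaminant, reads with a
single-nucleotide run longer than 10 nt, and reads with more than 10%
ambiguous (N) bases.  Rejection reasons are tallied in a fixed precedence
(length -> 5' contaminant -> homopolymer -> N fraction) so the tallies are
reproducible.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqio import normalize

#: rejection reason labels, in tally precedence order
REASON_NO_ADAPTER = "no_adapter"
REASON_LENGTH = "length"
REASON_5P_CONTAMINANT = "adapter5_contaminant"
REASON_HOMOPOLYMER = "homopolymer"
REASON_N_FRACTION = "n_fraction"


@dataclass
class FilterParams:
    """Cleaning thresholds; defaults are the pipeline's standard sRNA rules."""

    min_len: int = 10
    max_len: int = 30
    max_homopolymer: int = 10
    max_n_fraction: float = 0.10
    adapter3: str = ""
    adapter5: str = ""
    min_adapter_overlap: int = 8
    min_mean_quality: float | None = None  # optional, off by default

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ValueError("max_n_fraction must lie in [0, 1]")
        self.adapter3 = normalize(self.adapter3) if self.adapter3 else ""
        self.adapter5 = normalize(self.adapter5) if self.adapter5 else ""


@dataclass
class CleanRead:
    """A collapsed unique insert sequence with its per-library read count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("CleanRead count must be >= 1")


@dataclass
class LibraryStats:
    """Per-library read accounting in the shape of a sequencing summary table."""

    library_id: str
    raw_reads: int = 0
    clean_reads: int = 0
    length_filtered_reads: int = 0
    mapped_reads: int = 0
    length_filtered_unique_reads: int = 0
    mapped_unique_reads: int = 0

    @property
    def clean_percent(self) -> float:
        return 100.0 * self.clean_reads / self.raw_reads if self.raw_reads else 0.0


def _homopolymer_run(sequence: str) -> int:
    best = 0
    for match in re.finditer(r"(.)\1*", sequence):
        best = max(best, match.end() - match.start())
    return best


def trim_adapter3(sequence: str, params: FilterParams) -> str | None:
    """Cut a read at the first occurrence of the 3' adapter; None if absent.

    The adapter is recognized by an exact match of its first
    ``min_adapter_overlap`` bases (reads whose insert extends to the read
    end without reaching the adapter are rejected, since the insert
    boundary cannot be established).
    """
    if not params.adapter3:
        raise ValueError("trim_adapter3 requires a configured 3' adapter")
    if len(params.adapter3) < params.min_adapter_overlap:
        raise ValueError("adapter3 is shorter than min_adapter_overlap")
    probe = params.adapter3[: params.min_adapter_overlap]
    pos = normalize(sequence).find(probe)
    if pos < 0:
        return None
    return normalize(sequence)[:pos]


def _first_failure(seq: str, params: FilterParams) -> str | None:
    if not params.min_len <= len(seq) <= params.max_len:
        return REASON_LENGTH
    if params.adapter5 and len(params.adapter5) >= params.min_adapter_overlap:
        if seq.startswith(params.adapter5[-params.min_adapter_overlap:]):
            return REASON_5P_CONTAMINANT
    if _homopolymer_run(seq) > params.max_homopolymer:
        return REASON_HOMOPOLYMER
    if len(seq) and seq.count("N") / len(seq) > params.max_n_fraction:
        return REASON_N_FRACTION
    return None


def filter_reads(
    reads: Iterable[str], params: FilterParams
) -> tuple[list[str], Counter]:
    """Apply the cleaning rules to adapter-trimmed inserts.

    Returns the kept sequences (input order) and a tally of rejection
    reasons; kept + sum(tally) equals the input size.
    """
    kept: list[str] = []
    tally: Counter = Counter()
    for raw in reads:
        seq = normalize(raw)
        reason = _first_failure(seq, params)
        if reason is None:
            kept.append(seq)
        else:
            tally[reason] += 1
    return kept, tally


def collapse_unique(reads: Iterable[str]) -> list[CleanRead]:
    """Collapse reads to unique sequences with counts, lexicographic order."""
    counts = Counter(normalize(r) for r in reads)
    return [CleanRead(seq, n) for seq, n in sorted(counts.items())]


def collapse_counted(counts: Mapping[str, int]) -> list[CleanRead]:
    """Build collapsed reads from an existing sequence -> count map."""
    return [CleanRead(seq, n) for seq, n in sorted(counts.items()) if n > 0]


def filter_counted(
    counts: Mapping[str, int], params: FilterParams
) -> tuple[dict[str, int], Counter]:
    """Filter a pre-collapsed sequence->count map (weighted tally).

    Equivalent to :func:`filter_reads` on the expanded multiset; collapsing
    first lets deeply sequenced libraries be cleaned in one pass per unique
    sequence.
    """
    kept: dict[str, int] = {}
    tally: Counter = Counter()
    for raw, n in counts.items():
        seq = normalize(raw)
        reason = _first_failure(seq, params)
        if reason is None:
            kept[seq] = kept.get(seq, 0) + n
        else:
            tally[reason] += n
    return kept, tally


@dataclass
class SizeDistribution:
    """Read-length histogram (totals and unique sequences) over 10-30 nt."""

    min_len: int = 10
    max_len: int = 30
    total: dict[int, int] = field(default_factory=dict)
    unique: dict[int, int] = field(default_factory=dict)

    def lengths(self) -> range:
        return range(self.min_len, self.max_len + 1)


def size_distribution(
    reads: Sequence[CleanRead], min_len: int = 10, max_len: int = 30
) -> SizeDistribution:
    """Length histogram of collapsed reads, weighted (total) and unweighted (unique)."""
    dist = SizeDistribution(min_len, max_len)
    dist.total = {length: 0 for length in dist.lengths()}
    dist.unique = {length: 0 for length in dist.lengths()}
    for read in reads:
        length = len(read.sequence)
        if not min_len <= length <= max_len:
            raise ValueError(f"read length {length} outside [{min_len}, {max_len}]")
        dist.total[length] += read.count
        dist.unique[length] += 1
    return dist
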