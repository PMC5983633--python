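"""miRNA target prediction and degradome (PARE) cleavage validation.

Target sites are scored by ungapped antiparallel complementarity between
the miRNA and a transcript window: a G:U wobble or any other mismatch
costs 0.5 points, doubled when it falls at miRNA positions 2-13 (the
5'-seed-proximal core), and windows scoring at most 4 points pass the
screen.  Degradome read 5' ends are piled up on transcripts; the expected
cleavage position sits opposite miRNA position 10.  Each validated site
is placed in one of five categories by the rank of its 5'-end abundance
relative to the transcript's maximum and median signal.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from .seqio import SequenceRecord, normalize

WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "T"), ("T", "G")}  # G:U wobble on the canonical DNA alphabet

SYM_PAIR = "|"
SYM_WOBBLE = "o"
SYM_MISMATCH = "x"


@dataclass
class PenaltyParams:
    """Complementarity penalty scheme with a core-region multiplier."""

    gu_penalty: float = 0.5
    mismatch_penalty: float = 0.5
    core_start: int = 2  # 1-based miRNA positions, inclusive
    core_end: int = 13
    core_multiplier: float = 2.0
    score_cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.gu_penalty < 0 or self.mismatch_penalty < 0:
            raise ValueError("penalties must be non-negative")
        if self.core_start < 1 or self.core_end < self.core_start:
            raise ValueError("invalid core range")


@dataclass
class TargetSite:
    """A scored miRNA:transcript duplex at one transcript window."""

    mirna_id: str
    transcript_id: str
    start: int  # 0-based window interval on the transcript
    end: int
    pairing: str  # per miRNA position 5'->3': | (WC), o (G:U), x (mismatch)
    penalties: list[float] = field(default_factory=list)
    score: float = 0.0

    def accepted(self, params: PenaltyParams) -> bool:
        return self.score <= params.score_cutoff


def score_duplex(
    mirna: str,
    site: str,
    params: PenaltyParams | None = None,
    mirna_id: str = "",
    transcript_id: str = "",
    start: int = 0,
) -> TargetSite:
    """Score an ungapped antiparallel miRNA:site duplex.

    Both sequences are given 5'->3'; miRNA position i (1-based from the
    5' end) faces site position len(site) - i + 1.
    """
    params = params or PenaltyParams()
    m = normalize(mirna)
    s = normalize(site)
    if len(m) != len(s):
        raise ValueError(f"miRNA length {len(m)} != site length {len(s)}")
    pairing = []
    penalties = []
    for i, base in enumerate(m):  # i = miRNA position - 1
        partner = s[len(s) - 1 - i]
        duo = (base, partner)
        if duo in WC_PAIRS:
            sym, pen = SYM_PAIR, 0.0
        elif duo in GU_PAIRS:
            sym, pen = SYM_WOBBLE, params.gu_penalty
        else:
            sym, pen = SYM_MISMATCH, params.mismatch_penalty
        if pen and params.core_start <= i + 1 <= params.core_end:
            pen *= params.core_multiplier
        pairing.append(sym)
        penalties.append(pen)
    return TargetSite(
        mirna_id, transcript_id, start, start + len(m),
        "".join(pairing), penalties, sum(penalties),
    )


def scan_transcript(
    mirna: str,
    transcript: SequenceRecord | str,
    params: PenaltyParams | None = None,
    mirna_id: str = "",
) -> list[TargetSite]:
    """Score every window of the transcript; return accepted sites sorted by
    (score, position)."""
    params = params or PenaltyParams()
    if isinstance(transcript, SequenceRecord):
        tid, seq = transcript.id, transcript.sequence
    else:
        tid, seq = "", normalize(transcript)
    m = normalize(mirna)
    if len(seq) < len(m):
        return []
    sites = []
    for start in range(len(seq) - len(m) + 1):
        site = score_duplex(m, seq[start:start + len(m)], params,
                            mirna_id=mirna_id, transcript_id=tid, start=start)
        if site.accepted(params):
            sites.append(site)
    return sorted(sites, key=lambda s: (s.score, s.start))


@dataclass
class DegradomeProfile:
    """Per-position degradome read 5'-end counts on one transcript."""

    transcript_id: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, position: int, n: int = 1) -> None:
        self.counts[position] = self.counts.get(position, 0) + n


def map_degradome(
    reads: Iterable[str],
    transcripts: Sequence[SequenceRecord],
    prefix_len: int = 20,
) -> dict[str, DegradomeProfile]:
    """Pile up degradome read 5' ends on transcripts.

    Each read is matched by the exact occurrence of its first
    ``prefix_len`` nt (the informative 5' end of the cleavage fragment);
    every match on every transcript increments the 5'-end counter at the
    match start.
    """
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for rec in transcripts:
        seq = rec.sequence
        for pos in range(len(seq) - prefix_len + 1):
            index[seq[pos:pos + prefix_len]].append((rec.id, pos))
    profiles = {rec.id: DegradomeProfile(rec.id) for rec in transcripts}
    for read in reads:
        prefix = normalize(read)[:prefix_len]
        if len(prefix) < prefix_len:
            continue
        for tid, pos in index.get(prefix, ()):
            profiles[tid].add(pos)
    return profiles


def cleavage_position(site: TargetSite, mirna_len: int | None = None) -> int:
    """Transcript coordinate opposite miRNA position 10 (the 5' end of the
    3' cleavage fragment) under the antiparallel window convention."""
    length = mirna_len if mirna_len is not None else site.end - site.start
    return site.start + (length - 10)


class NoCleavageEvidence(ValueError):
    """The degradome profile has no reads at the proposed cleavage position."""


@dataclass
class CleavageCall:
    site: TargetSite
    position: int
    abundance: int
    transcript_max: int
    transcript_median: float
    category: int


def categorize(profile: DegradomeProfile, position: int) -> int:
    """Five-way cleavage category of a degradome signal at ``position``.

    Precedence: a single read at the site -> 5; otherwise unique transcript
    maximum -> 1; tied maximum -> 2; >= median -> 3; below median -> 4.
    The median is taken over positions carrying at least one read.
    """
    count = profile.counts.get(position, 0)
    if count == 0:
        raise NoCleavageEvidence(
            f"no degradome reads at {profile.transcript_id}:{position}"
        )
    if count == 1:
        return 5
    values = [v for v in profile.counts.values() if v >= 1]
    peak = max(values)
    if count == peak:
        return 1 if values.count(peak) == 1 else 2
    return 3 if count >= median(values) else 4


def call_cleavage(
    site: TargetSite, profile: DegradomeProfile
) -> CleavageCall:
    """Locate and categorize the expected cleavage signal for one target site."""
    pos = cleavage_position(site)
    values = [v for v in profile.counts.values() if v >= 1]
    return CleavageCall(
        site=site,
        position=pos,
        abundance=profile.counts.get(pos, 0),
        transcript_max=max(values) if values else 0,
        transcript_median=median(values) if values else 0.0,
        category=categorize(profile, pos),
    )
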