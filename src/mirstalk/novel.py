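"""Novel miRNA discovery: precursor excision, stability metrics, duplex support.

A candidate precursor is excised around a mapped read stack, folded, and
screened with the two classical lines of evidence for genuine Dicer
processing: (i) sequencing reads covering both the mature miRNA and its
star partner, positioned as a duplex with ~2-nt 3' overhangs under the
predicted structure; or, failing star support, (ii) detection of the
mature sequence in at least two independent libraries.  Hairpin stability
is summarized by MFE and by the minimal folding free energy index
MFEI = (|MFE| / precursor length x 100) / GC%, which separates miRNA
precursors from other structured ncRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .fold import FoldResult, fold_rna
from .mapping import Alignment, GenomeIndex
from .seqio import gc_percent, reverse_complement

#: precursor length range observed for plant pre-miRNAs (warning bounds)
MIN_PRECURSOR_LEN = 38
MAX_PRECURSOR_LEN = 292


@dataclass
class PrecursorCandidate:
    """An excised hairpin window with structure and stability metrics."""

    sequence: str
    chrom: str
    start: int  # 0-based half-open genomic interval of the window
    end: int
    strand: str
    mature_offset: int  # mature start within `sequence`
    mature_len: int
    arm: str  # "5p" | "3p"
    fold: FoldResult | None = None
    mfe: float | None = None  # kcal/mol if supplied; else pseudo-energy

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_percent(self.sequence)

    @property
    def mfei(self) -> float:
        if self.mfe is None:
            raise ValueError("candidate has no MFE; fold or supply one first")
        return compute_mfei(self.mfe, self.length, self.gc)

    def location(self) -> str:
        return f"{self.chrom}:{self.start + 1}..{self.end}"


@dataclass
class DuplexSupport:
    """Mature/star read evidence on one precursor."""

    mature: str
    star: str | None = None
    star_read_count: int = 0
    libraries_detected: set[str] = field(default_factory=set)
    overhang_ok: bool = False


@dataclass
class NovelCall:
    candidate: PrecursorCandidate
    support: DuplexSupport
    accepted: bool
    rule_fired: str  # star_supported | multi_library | rejected


def mature_length(sequence: str) -> int:
    """Length (LM) of a mature miRNA sequence in nucleotides."""
    if not sequence:
        raise ValueError("mature sequence is empty")
    return len(sequence)


def compute_mfei(mfe: float, precursor_len: int, gc: float) -> float:
    """MFEI = (|MFE| / precursor length x 100) / GC%.

    ``gc`` is a percentage (e.g. 38.10); the result is dimensionless.
    """
    if precursor_len <= 0:
        raise ValueError("precursor length must be positive")
    if gc <= 0:
        raise ValueError("MFEI undefined for GC% <= 0")
    return (abs(mfe) / precursor_len * 100.0) / gc


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding for display (matches printed report tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def excise_precursor(
    alignment: Alignment,
    index: GenomeIndex,
    flank: int = 70,
    lead: int = 15,
) -> list[PrecursorCandidate]:
    """Excise the two candidate hairpin windows around a read stack.

    One window assumes the mature sits on the 5' arm (long flank 3' of the
    read), the other on the 3' arm (long flank 5' of it); ``lead`` pads the
    short side.  Windows are clipped at scaffold boundaries and capped so
    the precursor never exceeds the expected maximum length.
    """
    chrom_seq = index.sequences[alignment.chrom]
    read_len = alignment.end - alignment.start
    flank = min(flank, MAX_PRECURSOR_LEN - read_len - lead)
    windows = []
    for arm, left, right in (("5p", lead, flank), ("3p", flank, lead)):
        if alignment.strand == "-":
            left, right = right, left
        start = max(0, alignment.start - left)
        end = min(len(chrom_seq), alignment.end + right)
        seq = chrom_seq[start:end]
        offset = alignment.start - start
        if alignment.strand == "-":
            seq = reverse_complement(seq)
            offset = end - alignment.end
        windows.append(
            PrecursorCandidate(
                seq, alignment.chrom, start, end, alignment.strand,
                offset, read_len, arm,
            )
        )
    return windows


def expected_star_interval(
    fold: FoldResult, mature_start: int, mature_end: int
) -> tuple[int, int] | None:
    """Predicted star interval for a mature arm under a 2-nt 3'-overhang duplex.

    The mature's paired positions (excluding its own 2-nt 3' overhang) are
    projected through the structure's pair table; the star then extends two
    further nt at its 3' end.  None when the mature arm is essentially
    unpaired.
    """
    table = fold.pair_table()
    core = range(mature_start, max(mature_start, mature_end - 2))
    paired = [i for i in core if table[i] >= 0]
    if len(paired) < max(4, len(core) // 2):
        return None
    # on a true duplex i + partner(i) is constant; the median diagonal is
    # robust to a few tie-broken off-diagonal pairs at the stem edges
    diagonals = sorted(i + table[i] for i in paired)
    diag = diagonals[len(diagonals) // 2]
    star_start = diag - (mature_end - 3)
    star_end = diag - mature_start + 1 + 2
    n = len(fold.structure)
    if star_start < 0 or star_end > n or star_end - star_start < 4:
        return None
    return star_start, star_end


def check_duplex(
    candidate: PrecursorCandidate,
    mature_start: int,
    mature_end: int,
    star_start: int,
    star_end: int,
    tolerance: int = 1,
) -> bool:
    """True iff the star interval matches the structure-implied duplex partner
    of the mature interval, allowing ``tolerance`` nt of slack per end."""
    if not (0 <= mature_start < mature_end <= candidate.length):
        raise ValueError("mature interval outside precursor")
    if candidate.fold is None:
        candidate.fold = fold_rna(candidate.sequence)
    expected = expected_star_interval(candidate.fold, mature_start, mature_end)
    if expected is None:
        return False
    exp_start, exp_end = expected
    return abs(star_start - exp_start) <= tolerance and \
        abs(star_end - exp_end) <= tolerance


def call_novel(
    candidate: PrecursorCandidate,
    support: DuplexSupport,
    min_libraries: int = 2,
) -> NovelCall:
    """Accept a candidate with star-duplex support, or with detection in at
    least ``min_libraries`` independent libraries; otherwise reject."""
    star_supported = support.star is not None and support.star_read_count > 0 \
        and support.overhang_ok
    if star_supported:
        return NovelCall(candidate, support, True, "star_supported")
    if len(support.libraries_detected) >= min_libraries:
        return NovelCall(candidate, support, True, "multi_library")
    return NovelCall(candidate, support, False, "rejected")


def first_nt_bias(matures: Iterable[str]) -> dict[str, float]:
    """Fraction of mature sequences starting with each of A/C/G/U."""
    counts = {"A": 0, "C": 0, "G": 0, "U": 0}
    total = 0
    for seq in matures:
        first = seq[0].upper().replace("T", "U")
        if first in counts:
            counts[first] += 1
            total += 1
    if total == 0:
        raise ValueError("no mature sequences supplied")
    return {nt: n / total for nt, n in counts.items()}


def precursor_report_row(
    name: str, candidate: PrecursorCandidate, mature: str, has_star: bool
) -> dict[str, object]:
    """One row of the novel-miRNA report table (LM/LP/GC%/MFE/MFEI columns)."""
    from .seqio import to_rna

    return {
        "miRNA": name,
        "sequence": to_rna(mature).lower(),
        "miRNA*": "Yes" if has_star else "No",
        "arm": candidate.arm,
        "LM": mature_length(mature),
        "location": candidate.location(),
        "strand": candidate.strand,
        "MFE": candidate.mfe,
        "LP": candidate.length,
        "GC%": round_half_up(candidate.gc, 2),
        "MFEI": round_half_up(candidate.mfei, 2),
    }
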