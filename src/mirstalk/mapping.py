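"""Exact (zero-mismatch) genome mapping and small-RNA annotation.

Reads are mapped to both strands by exact string matching via a
fixed-length seed index, which for 10-30 nt queries is equivalent to a
full-sensitivity aligner run with zero mismatches allowed.  Annotation of
known miRNAs requires identity to a reference mature sequence that is
itself contained in its hairpin; everything else is classified against
ordered per-class reference sets with a fixed precedence hierarchy.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .reads import CleanRead, LibraryStats
from .seqio import SequenceRecord, normalize, reverse_complement

#: annotation hierarchy, highest precedence first
CLASS_HIERARCHY = (
    "known_miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "scRNA",
    "repeat",
    "nat_siRNA",
    "exon",
    "intron",
    "novel_candidate",
)
CLASS_OTHER = "other"


@dataclass(frozen=True)
class Alignment:
    """A zero-mismatch placement of a read on the genome (0-based, half-open)."""

    read: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end - self.start != len(self.read):
            raise ValueError("alignment interval length != read length")


class GenomeIndex:
    """Seed-based substring index over a genome for exact-match queries.

    Stores every ``seed_len``-mer position; a query is located by seed
    lookup plus full-length verification, so results are exactly the
    zero-mismatch occurrence set.
    """

    def __init__(self, genome: Iterable[SequenceRecord], seed_len: int = 10):
        self.seed_len = seed_len
        self.sequences: dict[str, str] = {}
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for rec in genome:
            self.sequences[rec.id] = rec.sequence
        if not self.sequences:
            raise ValueError("cannot index an empty genome")
        for chrom, seq in self.sequences.items():
            for pos in range(len(seq) - seed_len + 1):
                self._seeds[seq[pos:pos + seed_len]].append((chrom, pos))

    def occurrences(self, query: str) -> list[tuple[str, int]]:
        """All exact plus-strand occurrence positions of ``query``."""
        if len(query) < self.seed_len:
            raise ValueError(f"query shorter than seed length {self.seed_len}")
        hits = []
        for chrom, pos in self._seeds.get(query[: self.seed_len], ()):
            if self.sequences[chrom][pos:pos + len(query)] == query:
                hits.append((chrom, pos))
        return hits


def build_index(genome: Sequence[SequenceRecord], seed_len: int = 10) -> GenomeIndex:
    return GenomeIndex(genome, seed_len)


def map_exact(read: str, index: GenomeIndex) -> list[Alignment]:
    """All zero-mismatch alignments of a read on both genome strands.

    Sorted by (chrom, start, strand); a read counts as mapped iff the
    result is non-empty.
    """
    seq = normalize(read)
    hits = [
        Alignment(seq, chrom, pos, pos + len(seq), "+")
        for chrom, pos in index.occurrences(seq)
    ]
    rc = reverse_complement(seq)
    hits += [
        Alignment(seq, chrom, pos, pos + len(seq), "-")
        for chrom, pos in index.occurrences(rc)
    ]
    return sorted(hits, key=lambda a: (a.chrom, a.start, a.strand))


@dataclass(frozen=True)
class KnownHit:
    mature_id: str
    family: str


class KnownReference:
    """Reference mature + hairpin sets (miRBase-style) for known-miRNA calls."""

    def __init__(self, mature: Sequence[SequenceRecord],
                 hairpin: Sequence[SequenceRecord]):
        hairpins = {rec.id: rec.sequence for rec in hairpin}
        self._by_seq: dict[str, KnownHit] = {}
        for rec in mature:
            hp_id = _hairpin_id_for(rec.id, hairpins)
            if hp_id is None:
                raise ValueError(f"mature {rec.id!r} has no corresponding hairpin record")
            if rec.sequence in hairpins[hp_id]:
                self._by_seq.setdefault(rec.sequence, KnownHit(rec.id, _family(rec.id)))

    def lookup(self, sequence: str) -> KnownHit | None:
        return self._by_seq.get(normalize(sequence))


def _hairpin_id_for(mature_id: str, hairpins: Mapping[str, str]) -> str | None:
    """Match a mature id to its hairpin: exact id, else id minus a -5p/-3p suffix."""
    if mature_id in hairpins:
        return mature_id
    base = mature_id
    for suffix in ("-5p", "-3p"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return base if base in hairpins else None


def _family(mature_id: str) -> str:
    """Family from a miRBase-style id: strip species prefix and arm/variant suffix."""
    name = mature_id.split("-", 1)[1] if "-" in mature_id else mature_id
    for suffix in ("-5p", "-3p"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name.rstrip("abcdefghijklmnopqrstuvwxyz")


def annotate_known(read: str, reference: KnownReference) -> KnownHit | None:
    """Known-miRNA call: identity to a reference mature contained in its hairpin."""
    return reference.lookup(read)


def classify_read(
    read: str,
    mapped: bool,
    known: KnownHit | None,
    annotation_refs: Sequence[tuple[str, Sequence[SequenceRecord]]] = (),
) -> str:
    """Assign the single annotation class of a mapped read.

    The first matching class in the fixed hierarchy wins; reference-set
    membership is an exact-substring test (the read must occur within a
    reference sequence of that class).  Unmapped reads are ``other``;
    mapped reads matching nothing are ``novel_candidate``.
    """
    if not mapped:
        return CLASS_OTHER
    if known is not None:
        return "known_miRNA"
    ref_map = {cls: recs for cls, recs in annotation_refs}
    seq = normalize(read)
    for cls in CLASS_HIERARCHY[1:-1]:
        for rec in ref_map.get(cls, ()):
            if seq in rec.sequence:
                return cls
    return "novel_candidate"


def library_mapping_stats(
    library_id: str,
    reads: Sequence[CleanRead],
    alignments: Mapping[str, Sequence[Alignment]],
    raw_reads: int = 0,
    clean_reads: int = 0,
) -> LibraryStats:
    """Sequencing-summary-style accounting for one library.

    Total columns weight each unique sequence by its count; unique columns
    count distinct sequences.  A multi-locus sequence is counted once as
    mapped.
    """
    stats = LibraryStats(library_id, raw_reads=raw_reads, clean_reads=clean_reads)
    for read in reads:
        stats.length_filtered_reads += read.count
        stats.length_filtered_unique_reads += 1
        if alignments.get(read.sequence):
            stats.mapped_reads += read.count
            stats.mapped_unique_reads += 1
    return stats
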