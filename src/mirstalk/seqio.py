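"""Sequence records, FASTA/FASTQ I/O, and elementary sequence operations.

All sequences are stored on a canonical upper-case DNA alphabet (``T``);
``U`` is accepted on input and converted losslessly, and miRNA-facing
reports can render the RNA view with :func:`to_rna`.  Parsing and writing
of FASTA/FASTQ delegate to Biopython; this module adds the record-level
validation the rest of the pipeline relies on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceFormatError(ValueError):
    """A record violates the FASTA/FASTQ contract (empty sequence, bad length...)."""


def normalize(sequence: str) -> str:
    """Upper-case a sequence and convert RNA ``U`` to the canonical DNA ``T``."""
    return sequence.upper().replace("U", "T")


def to_rna(sequence: str) -> str:
    """Render a canonical DNA-alphabet sequence in its RNA (``U``) view."""
    return sequence.upper().replace("T", "U")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence on the canonical {A,C,G,T,N} alphabet."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        if not self.sequence:
            raise SequenceFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise SequenceFormatError(
                f"record {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FastqRecord:
    """A sequencing read: a :class:`SequenceRecord` plus its Phred+33 quality string."""

    record: SequenceRecord
    quality: str = field(repr=False, default="")

    def __post_init__(self) -> None:
        if len(self.quality) != len(self.record.sequence):
            raise SequenceFormatError(
                f"record {self.record.id!r}: sequence length "
                f"{len(self.record.sequence)} != quality length {len(self.quality)}"
            )


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) FASTA file into normalized records."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise SequenceFormatError(f"record {rec.id!r} has an empty sequence")
        desc = rec.description
        if desc == rec.id:
            desc = ""
        elif desc.startswith(rec.id + " "):
            desc = desc[len(rec.id) + 1:]
        records.append(SequenceRecord(rec.id, str(rec.seq), desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike,
                rna: bool = False) -> None:
    """Write records as single-line FASTA; ``rna=True`` renders U instead of T."""
    bio = [
        _BioRecord(Seq(to_rna(r.sequence) if rna else r.sequence), id=r.id,
                   description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=None)
        writer.write_file(bio)


def read_fastq(path: str | os.PathLike) -> list[FastqRecord]:
    """Read 4-line FASTQ records (Phred+33); validates sequence/quality lengths."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out: list[FastqRecord] = []
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle]
    if len(lines) % 4 and any(lines[4 * (len(lines) // 4):]):
        raise SequenceFormatError(
            f"{path}: truncated FASTQ record at index {len(lines) // 4}"
        )
    for i in range(0, len(lines) - len(lines) % 4, 4):
        header, seq, plus, qual = lines[i:i + 4]
        idx = i // 4
        if not header.startswith("@") or not plus.startswith("+"):
            raise SequenceFormatError(f"{path}: malformed FASTQ record at index {idx}")
        if len(seq) != len(qual):
            raise SequenceFormatError(
                f"{path}: record index {idx}: sequence/quality length mismatch"
            )
        name, _, desc = header[1:].partition(" ")
        out.append(FastqRecord(SequenceRecord(name, seq, desc), qual))
    return out


def write_fastq(records: Iterable[FastqRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f"@{rec.record.id}\n{rec.record.sequence}\n+\n{rec.quality}\n")


def reverse_complement(sequence: str) -> str:
    """Reverse complement on the canonical alphabet; ``N`` maps to ``N``."""
    seq = normalize(sequence)
    for pos, char in enumerate(seq):
        if char not in VALID_ALPHABET:
            raise ValueError(f"invalid character {char!r} at position {pos}")
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(sequence: str) -> float:
    """GC content as a percentage of the non-N length.

    Guanine and cytosine counts are divided by the number of unambiguous
    bases, so masked (N) positions affect neither numerator nor denominator.
    """
    seq = normalize(sequence)
    if not seq:
        raise ValueError("gc_percent of an empty sequence is undefined")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("sequence contains only N characters")
    return 100.0 * (seq.count("G") + seq.count("C")) / denom
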