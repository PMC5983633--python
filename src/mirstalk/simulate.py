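"""Seeded synthetic data emulating a plant sRNA-seq + degradome experiment.

The generator plants miRNA hairpins (mature + loop + star, exactly
complementary with 2-nt 3' overhangs) in a random genome, simulates the
2-tissue x 3-treatment x 3-replicate library design with
negative-binomial counts and configured log2 fold-changes, appends
sequencing adapters, and emits a degradome library with 5'-end peaks
constructed to realize each of the five cleavage categories.  Every
emitted dataset is paired with a ground-truth manifest so recovery can be
scored exactly.  All randomness flows from one integer seed through
named substreams, so adding an emitter never perturbs another's output.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import LibraryMeta
from .seqio import FastqRecord, SequenceRecord, reverse_complement, write_fastq

# substream ids: one per emitter so streams stay independent
_STREAMS = {
    "genome": 1, "hairpins": 2, "abundance": 3, "counts": 4,
    "background": 5, "degradome": 6, "decoys": 7,
}

TISSUE_CODES = {"stem": "S", "root": "R", "leaf": "L"}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the synthetic experiment."""

    seed: int = 0
    n_scaffolds: int = 2
    scaffold_len: int = 60_000
    n_known: int = 20
    n_novel: int = 20
    n_decoys: int = 10
    tissues: tuple[str, ...] = ("stem", "root")
    treatments: tuple[str, ...] = ("C", "S", "L")
    replicates: int = 3
    depth: int = 1_000_000
    background_fraction: float = 0.02
    no_adapter_fraction: float = 0.01
    star_fraction: float = 0.10
    dispersion: float = 0.05
    n_de: int = 20  # planted differential miRNAs (half up, half down)
    de_log2fc: float = 2.0  # 4-fold changes
    de_tissue: str = "stem"
    de_treatment: str = "S"  # effect applied in this treatment vs control C
    mature_lengths: tuple[int, ...] = (21, 22, 24)
    mature_length_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    loop_len: int = 8
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    error_rate: float = 0.0
    # degradome design: sites per intended category, read length, transcripts
    degradome_sites_per_category: int = 5
    degradome_read_len: int = 20
    transcript_len: int = 600
    # background insert length distribution: modal 24 then 21, long tail
    # (a small mass above 30 nt exercises the length filter)
    bg_length_values: tuple[int, ...] = tuple(range(15, 35))
    bg_length_probs: tuple[float, ...] = (
        0.01, 0.01, 0.02, 0.03, 0.04, 0.05, 0.20, 0.08, 0.10, 0.30,
        0.05, 0.03, 0.02, 0.02, 0.02, 0.005, 0.005, 0.005, 0.0025, 0.0025,
    )

    def library_ids(self) -> list[str]:
        return [
            f"{treat}{TISSUE_CODES[tissue]}{rep}"
            for tissue in self.tissues
            for treat in self.treatments
            for rep in range(1, self.replicates + 1)
        ]

    def library_meta(self, total_clean: Mapping[str, int] | None = None
                     ) -> dict[str, LibraryMeta]:
        meta = {}
        for tissue in self.tissues:
            for treat in self.treatments:
                for rep in range(1, self.replicates + 1):
                    lib = f"{treat}{TISSUE_CODES[tissue]}{rep}"
                    meta[lib] = LibraryMeta(
                        lib, tissue, treat, rep,
                        (total_clean or {}).get(lib, self.depth),
                    )
        return meta

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed % 2**31, _STREAMS[stream]])


@dataclass
class PlantedHairpin:
    name: str
    kind: str  # known | novel | decoy
    chrom: str
    start: int  # 0-based half-open precursor interval on the plus strand
    end: int
    strand: str
    mature: str  # canonical DNA alphabet, 5'->3' of the miRNA
    star: str | None
    arm: str
    precursor: str  # strand-resolved 5'->3' precursor sequence


@dataclass
class PlantedSite:
    mirna: str  # miRNA name
    mature: str
    transcript_id: str
    window_start: int  # 0-based site window on the transcript
    cleavage_pos: int
    category: int


@dataclass
class GroundTruth:
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    expected_counts: pd.DataFrame | None = None  # mature sequence x library
    de_true: dict[str, float] = field(default_factory=dict)  # name -> log2FC
    de_comparison: tuple[str, str] = ("", "")  # (control treatment, treated)
    sites: list[PlantedSite] = field(default_factory=list)
    names: dict[str, str] = field(default_factory=dict)  # mature seq -> name

    def by_kind(self, kind: str) -> list[PlantedHairpin]:
        return [h for h in self.hairpins if h.kind == kind]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int,
                gc: float = 0.5) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=probs).tobytes().decode()


def _make_mature(rng: np.random.Generator, length: int) -> str:
    """A GC-rich mature sequence with the plant 5'-U first-nucleotide bias."""
    seq = _random_seq(rng, length, gc=0.55)
    if rng.random() < 0.5:
        seq = "T" + seq[1:]
    return seq


def build_precursor(mature: str, loop_len: int = 8) -> tuple[str, str]:
    """Precursor = mature + loop + star with exact 2-nt 3' overhang geometry.

    The star pairs the mature core (all but its last two nt) exactly and
    adds its own two unpaired 3' nt; the loop is non-pairing (A-rich) so
    the maximum-weight fold is the intended stem.
    """
    loop = "A" * loop_len
    star = reverse_complement(mature[:-2]) + "AC"
    return mature + loop + star, star


def make_genome(config: SimulationConfig) -> tuple[list[SequenceRecord], GroundTruth]:
    """Random genome with non-overlapping planted hairpin loci and decoy 21-mers."""
    rng = config.rng("genome")
    hp_rng = config.rng("hairpins")
    truth = GroundTruth()

    scaffolds = {
        f"scaffold{i + 1}": bytearray(
            _random_seq(rng, config.scaffold_len).encode()
        )
        for i in range(config.n_scaffolds)
    }
    n_loci = config.n_known + config.n_novel + config.n_decoys
    if n_loci == 0:
        return [SequenceRecord(c, bytes(s).decode())
                for c, s in scaffolds.items()], truth

    # evenly spaced slots with jitter: deterministic and overlap-free
    per_scaffold = -(-n_loci // config.n_scaffolds)
    slot = config.scaffold_len // (per_scaffold + 1)
    if slot < 400:
        raise ValueError("scaffolds too short to place the requested hairpins")
    names = (
        [f"peu-sim-miR{i + 1}" for i in range(config.n_known)]
        + [f"miR-sim-n{i + 1}" for i in range(config.n_novel)]
        + [f"decoy{i + 1}" for i in range(config.n_decoys)]
    )
    kinds = (["known"] * config.n_known + ["novel"] * config.n_novel
             + ["decoy"] * config.n_decoys)

    for i, (name, kind) in enumerate(zip(names, kinds)):
        chrom = f"scaffold{i % config.n_scaffolds + 1}"
        slot_idx = i // config.n_scaffolds
        pos = slot * (slot_idx + 1) + int(hp_rng.integers(0, slot // 4))
        length = int(hp_rng.choice(config.mature_lengths,
                                   p=config.mature_length_probs))
        mature = _make_mature(hp_rng, length)
        strand = "+" if hp_rng.random() < 0.5 else "-"
        if kind == "decoy":
            insert, star, arm = mature, None, "5p"
        else:
            insert, star = build_precursor(mature, config.loop_len)
            arm = "5p"
        genomic = insert if strand == "+" else reverse_complement(insert)
        scaffolds[chrom][pos:pos + len(genomic)] = genomic.encode()
        # neutral flanking bases so reads cannot extend past the locus into
        # an accidental second (antisense) exact match
        scaffolds[chrom][pos - 2:pos] = b"AA"
        scaffolds[chrom][pos + len(genomic):pos + len(genomic) + 2] = b"AA"
        truth.hairpins.append(PlantedHairpin(
            name, kind, chrom, pos, pos + len(genomic), strand,
            mature, star, arm, insert,
        ))
        truth.names[mature] = name
    genome = [SequenceRecord(c, bytes(s).decode()) for c, s in scaffolds.items()]
    return genome, truth


def known_references(truth: GroundTruth) -> tuple[list[SequenceRecord],
                                                  list[SequenceRecord]]:
    """miRBase-style mature and hairpin reference sets for the planted knowns.

    Both duplex arms are registered (the star strand as ``<name>-3p``), as
    miRBase does for well-characterized precursors.
    """
    mature, hairpin = [], []
    for hp in truth.by_kind("known"):
        mature.append(SequenceRecord(f"{hp.name}-5p", hp.mature))
        if hp.star:
            mature.append(SequenceRecord(f"{hp.name}-3p", hp.star))
        hairpin.append(SequenceRecord(hp.name, hp.precursor))
    return mature, hairpin


def _abundance_table(config: SimulationConfig, truth: GroundTruth) -> pd.Series:
    """Baseline relative abundance (mean TPM at depth) per expressed mature."""
    rng = config.rng("abundance")
    expressed = [h for h in truth.hairpins if h.kind != "decoy"]
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=len(expressed))
    weights /= weights.sum()
    budget = config.depth * (1 - config.background_fraction) \
        / (1 + config.star_fraction)
    return pd.Series(weights * budget, index=[h.name for h in expressed])


def simulate_libraries(
    config: SimulationConfig,
    genome: Sequence[SequenceRecord],
    truth: GroundTruth,
) -> dict[str, Counter]:
    """Per-library collapsed read multisets (sequence -> count).

    Reads are insert + 3' adapter; miRNA counts are NB(mean, dispersion)
    around TPM-scaled means with the configured fold-changes applied in
    the treated condition; star reads accompany mature reads at
    ``star_fraction``; background reads are random genomic substrings.
    Also fills ``truth.expected_counts`` and ``truth.de_true``.
    """
    rng = config.rng("counts")
    bg_rng = config.rng("background")
    dec_rng = config.rng("decoys")
    meta = config.library_meta()
    lib_ids = config.library_ids()
    baseline = _abundance_table(config, truth)

    expressed = [h for h in truth.hairpins if h.kind != "decoy"]
    de_candidates = [h.name for h in expressed]
    n_de = min(config.n_de, len(de_candidates))
    truth.de_true = {
        name: (config.de_log2fc if i % 2 == 0 else -config.de_log2fc)
        for i, name in enumerate(de_candidates[:n_de])
    }
    truth.de_comparison = ("C", config.de_treatment)

    inv_disp = 1.0 / config.dispersion if config.dispersion > 0 else None

    def nb_draw(mean: np.ndarray) -> np.ndarray:
        mean = np.maximum(mean, 1e-9)
        if inv_disp is None:
            return rng.poisson(mean)
        p = inv_disp / (inv_disp + mean)
        return rng.negative_binomial(inv_disp, p)

    libraries: dict[str, Counter] = {}
    counts_table = pd.DataFrame(0, index=[h.name for h in expressed],
                                columns=lib_ids, dtype=int)
    genome_seqs = {rec.id: rec.sequence for rec in genome}
    forbidden: dict[str, list[tuple[int, int]]] = {}
    for hp in truth.hairpins:
        forbidden.setdefault(hp.chrom, []).append((hp.start - 5, hp.end + 5))

    for lib in lib_ids:
        m = meta[lib]
        scale = m.total_clean_reads / config.depth if config.depth else 0.0
        means = baseline.copy() * scale
        if m.tissue == config.de_tissue and m.treatment == config.de_treatment:
            for name, lfc in truth.de_true.items():
                means[name] *= 2.0 ** lfc
        counts = nb_draw(means.to_numpy())
        reads: Counter = Counter()
        for hp, n in zip(expressed, counts):
            if n <= 0:
                continue
            counts_table.loc[hp.name, lib] = int(n)
            reads[hp.mature + config.adapter3] += int(n)
            if hp.star:
                n_star = int(rng.binomial(n, config.star_fraction))
                if n_star:
                    reads[hp.star + config.adapter3] += n_star
        _add_background(reads, config, genome_seqs, bg_rng, forbidden)
        libraries[lib] = reads

    # decoy reads: one library only, enough to form a candidate stack
    decoys = truth.by_kind("decoy")
    if decoys:
        lib = lib_ids[0]
        for hp in decoys:
            libraries[lib][hp.mature + config.adapter3] += 50

    if config.error_rate > 0:
        libraries = {
            lib: _mutate(reads, config.error_rate, config.rng("counts"))
            for lib, reads in libraries.items()
        }
    truth.expected_counts = counts_table
    return libraries


def _add_background(reads: Counter, config: SimulationConfig,
                    genome: Mapping[str, str], rng: np.random.Generator,
                    forbidden: Mapping[str, Sequence[tuple[int, int]]] = ()
                    ) -> None:
    """Random genomic degradation reads, avoiding planted locus footprints
    (background reads model fragments of other RNA species, not miRNAs)."""
    n_bg = int(config.depth * config.background_fraction)
    if n_bg == 0:
        return
    chroms = list(genome)
    chrom_idx = rng.integers(0, len(chroms), size=n_bg)
    lengths = rng.choice(np.array(config.bg_length_values), size=n_bg,
                         p=np.array(config.bg_length_probs)
                         / sum(config.bg_length_probs))
    starts = rng.random(size=n_bg)
    no_adapter = rng.random(size=n_bg) < config.no_adapter_fraction
    for ci, length, frac, bare in zip(chrom_idx, lengths, starts, no_adapter):
        chrom = chroms[ci]
        seq = genome[chrom]
        pos = int(frac * (len(seq) - int(length)))
        end = pos + int(length)
        if any(pos < f_end and end > f_start
               for f_start, f_end in (forbidden or {}).get(chrom, ())):
            continue
        insert = seq[pos:end]
        reads[insert if bare else insert + config.adapter3] += 1


def _mutate(reads: Counter, rate: float, rng: np.random.Generator) -> Counter:
    out: Counter = Counter()
    for seq, n in reads.items():
        for _ in range(n):
            chars = list(seq)
            hits = np.nonzero(rng.random(len(chars)) < rate)[0]
            for i in hits:
                chars[i] = "ACGT"[int(rng.integers(0, 4))]
            out["".join(chars)] += 1
    return out


def simulate_degradome(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[list[SequenceRecord], Counter]:
    """Transcripts with planted target sites plus degradome 5'-end reads.

    Each intended category k in 1..5 gets ``degradome_sites_per_category``
    transcripts whose 5'-end profile realizes that category at the
    position opposite miRNA position 10 of the planted site.  Fills
    ``truth.sites``.
    """
    rng = config.rng("degradome")
    planted = [h for h in truth.hairpins if h.kind != "decoy"]
    if not planted:
        return [], Counter()
    transcripts: list[SequenceRecord] = []
    reads: Counter = Counter()
    read_len = config.degradome_read_len
    site_idx = 0
    for category in (1, 2, 3, 4, 5):
        for _ in range(config.degradome_sites_per_category):
            hp = planted[site_idx % len(planted)]
            site_idx += 1
            tid = f"transcript{site_idx}"
            seq = _random_seq(rng, config.transcript_len)
            window_start = int(rng.integers(100, config.transcript_len - 200))
            site_seq = reverse_complement(hp.mature)
            seq = seq[:window_start] + site_seq \
                + seq[window_start + len(site_seq):]
            cleave = window_start + len(hp.mature) - 10
            profile = _category_profile(category, cleave,
                                        config.transcript_len, rng)
            for pos, count in profile.items():
                reads[seq[pos:pos + read_len]] += count
            transcripts.append(SequenceRecord(tid, seq))
            truth.sites.append(PlantedSite(
                hp.name, hp.mature, tid, window_start, cleave, category,
            ))
    return transcripts, reads


def _category_profile(category: int, cleave: int, tlen: int,
                      rng: np.random.Generator) -> dict[int, int]:
    """5'-end count profile realizing one cleavage category by construction."""
    def others(n: int) -> list[int]:
        chosen: list[int] = []
        while len(chosen) < n:
            pos = int(rng.integers(0, tlen - 40))
            if abs(pos - cleave) > 3 and all(abs(pos - c) > 3 for c in chosen):
                chosen.append(pos)
        return chosen

    if category == 1:  # unique maximum at the cleavage site
        a, b = others(2)
        return {cleave: 10, a: 3, b: 2}
    if category == 2:  # tied maximum
        a, b = others(2)
        return {cleave: 8, a: 8, b: 2}
    if category == 3:  # below the max but >= median
        a, b, c = others(3)
        return {cleave: 5, a: 9, b: 3, c: 2}  # median of {5,9,3,2} = 4 <= 5
    if category == 4:  # below the median
        a, b, c = others(3)
        return {cleave: 2, a: 9, b: 8, c: 7}  # median 7.5 > 2
    if category == 5:  # single read at the site
        (a,) = others(1)
        return {cleave: 1, a: 9}
    raise ValueError(f"unknown category {category}")


def expand_reads(reads: Mapping[str, int], prefix: str = "read") -> list[FastqRecord]:
    """Expand a collapsed multiset into FASTQ records (qualities all 'I')."""
    out = []
    i = 0
    for seq in sorted(reads):
        for _ in range(reads[seq]):
            out.append(FastqRecord(SequenceRecord(f"{prefix}{i}", seq),
                                   "I" * len(seq)))
            i += 1
    return out


def write_library_fastq(reads: Mapping[str, int], path) -> None:
    write_fastq(expand_reads(reads), path)
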