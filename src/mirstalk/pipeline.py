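"""End-to-end orchestration: filter -> map -> annotate -> novel -> quant -> DE.

The pipeline consumes per-library read multisets (collapsed
sequence -> count maps, the exact representation of a FASTQ library),
runs each stage deterministically, and returns a result bundle with
per-library statistics, annotation tallies, novel-miRNA calls, the count
matrix, and differential-expression tables.  Degradome target validation
is a separate entry point (:func:`validate_targets`) because the
degradome library is pooled across the design rather than per-library.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import mapping as mp
from . import novel as nv
from . import reads as rd
from . import targeting as tg
from .expression import CountMatrix, DEResult, LibraryMeta, de_test
from .seqio import SequenceRecord

logger = logging.getLogger("mirstalk")


@dataclass
class PipelineParams:
    filter_params: rd.FilterParams = field(default_factory=rd.FilterParams)
    seed_len: int = 10
    flank: int = 70
    min_stack_reads: int = 5  # aggregate depth for a read stack to exist
    min_novel_reads: int = 30  # aggregate expression floor for candidates
    min_star_reads: int = 5
    star_tolerance: int = 1
    min_libraries: int = 2
    cluster_gap: int = 30
    penalty_params: tg.PenaltyParams = field(default_factory=tg.PenaltyParams)


@dataclass
class NovelLocus:
    """An accepted novel miRNA locus with its mature sequence and evidence."""

    name: str
    mature: str
    call: nv.NovelCall
    total_reads: int
    libraries: set[str]


@dataclass
class PipelineResult:
    library_stats: dict[str, rd.LibraryStats]
    size_distributions: dict[str, rd.SizeDistribution]
    rejections: dict[str, Counter]
    known_counts: pd.DataFrame  # known mature id x library
    annotation_tally: Counter
    novel_loci: list[NovelLocus]
    rejected_candidates: list[nv.NovelCall]
    count_matrix: CountMatrix | None = None
    de_results: dict[str, list[DEResult]] = field(default_factory=dict)


def _clean_libraries(
    libraries: Mapping[str, Mapping[str, int]], params: PipelineParams
) -> tuple[dict[str, dict[str, int]], dict[str, Counter], dict[str, int]]:
    """Trim 3' adapters and apply the cleaning filters, library by library."""
    kept: dict[str, dict[str, int]] = {}
    tallies: dict[str, Counter] = {}
    clean_totals: dict[str, int] = {}
    fp = params.filter_params
    for lib, reads in libraries.items():
        trimmed: Counter = Counter()
        tally: Counter = Counter()
        for seq, n in reads.items():
            insert = rd.trim_adapter3(seq, fp) if fp.adapter3 else seq
            if insert is None:
                tally[rd.REASON_NO_ADAPTER] += n
            else:
                trimmed[insert] += n
        clean_totals[lib] = sum(trimmed.values())
        filtered, reason_tally = rd.filter_counted(trimmed, fp)
        tally.update(reason_tally)
        kept[lib] = filtered
        tallies[lib] = tally
        logger.info("filter %s: kept %d reads (%d unique)", lib,
                    sum(filtered.values()), len(filtered))
    return kept, tallies, clean_totals


def run_pipeline(
    genome: Sequence[SequenceRecord],
    libraries: Mapping[str, Mapping[str, int]],
    library_meta: Mapping[str, LibraryMeta] | None = None,
    known_mature: Sequence[SequenceRecord] = (),
    known_hairpin: Sequence[SequenceRecord] = (),
    annotation_refs: Sequence[tuple[str, Sequence[SequenceRecord]]] = (),
    params: PipelineParams | None = None,
    comparisons: Mapping[str, tuple[Sequence[str], Sequence[str]]] | None = None,
) -> PipelineResult:
    """Run filtering, mapping, annotation, novel-miRNA discovery, and DE."""
    params = params or PipelineParams()
    kept, tallies, clean_totals = _clean_libraries(libraries, params)

    index = mp.build_index(genome, params.seed_len)
    reference = (mp.KnownReference(known_mature, known_hairpin)
                 if known_mature else None)

    # per-sequence aggregation across libraries
    known_rows: dict[str, dict[str, int]] = defaultdict(dict)
    tally = Counter()
    agg_count: Counter = Counter()
    agg_libs: dict[str, set] = defaultdict(set)
    align_cache: dict[str, list[mp.Alignment]] = {}
    lib_stats: dict[str, rd.LibraryStats] = {}
    size_dists: dict[str, rd.SizeDistribution] = {}

    for lib, seqs in kept.items():
        collapsed = rd.collapse_counted(seqs)
        size_dists[lib] = rd.size_distribution(collapsed)
        alignments: dict[str, list[mp.Alignment]] = {}
        for read in collapsed:
            seq = read.sequence
            if seq not in align_cache:
                align_cache[seq] = mp.map_exact(seq, index)
            alignments[seq] = align_cache[seq]
            if not alignments[seq]:
                tally[mp.CLASS_OTHER] += 1
                continue
            hit = reference.lookup(seq) if reference else None
            if hit is not None:
                known_rows[hit.mature_id][lib] = \
                    known_rows[hit.mature_id].get(lib, 0) + read.count
                tally["known_miRNA"] += 1
                continue
            cls = mp.classify_read(seq, True, None, annotation_refs)
            tally[cls] += 1
            if cls == "novel_candidate":
                agg_count[seq] += read.count
                agg_libs[seq].add(lib)
        raw_total = sum(libraries[lib].values())
        lib_stats[lib] = mp.library_mapping_stats(
            lib, collapsed, alignments,
            raw_reads=raw_total, clean_reads=clean_totals[lib],
        )

    known_counts = pd.DataFrame(known_rows).T.fillna(0).astype(int) \
        if known_rows else pd.DataFrame()
    novel_loci, rejected = _discover_novel(
        index, agg_count, agg_libs, align_cache, params,
    )

    result = PipelineResult(
        library_stats=lib_stats,
        size_distributions=size_dists,
        rejections=tallies,
        known_counts=known_counts,
        annotation_tally=tally,
        novel_loci=novel_loci,
        rejected_candidates=rejected,
    )

    if library_meta is not None:
        result.count_matrix = build_count_matrix(
            kept, known_counts, novel_loci, library_meta, clean_totals,
        )
        if comparisons:
            for label, (group_a, group_b) in comparisons.items():
                result.de_results[label] = de_test(
                    result.count_matrix, group_a, group_b, comparison=label,
                )
    return result


def _discover_novel(
    index: mp.GenomeIndex,
    agg_count: Counter,
    agg_libs: Mapping[str, set],
    align_cache: Mapping[str, list[mp.Alignment]],
    params: PipelineParams,
) -> tuple[list[NovelLocus], list[nv.NovelCall]]:
    """Cluster unannotated read stacks and call novel miRNA loci."""
    # place every stack (seq with its alignments); cluster by genomic overlap;
    # sequences below the stack-depth floor are background, not stacks
    placed: list[tuple[mp.Alignment, str]] = []
    for seq, count in agg_count.items():
        if count < params.min_stack_reads:
            continue
        for aln in align_cache[seq]:
            placed.append((aln, seq))
    placed.sort(key=lambda x: (x[0].chrom, x[0].strand, x[0].start))

    clusters: list[list[tuple[mp.Alignment, str]]] = []
    for aln, seq in placed:
        if clusters:
            last = clusters[-1][-1][0]
            if (aln.chrom, aln.strand) == (last.chrom, last.strand) and \
                    aln.start - last.end <= params.cluster_gap:
                clusters[-1].append((aln, seq))
                continue
        clusters.append([(aln, seq)])

    loci: list[NovelLocus] = []
    rejected: list[nv.NovelCall] = []
    n = 0
    for cluster in clusters:
        members = {seq for _, seq in cluster}
        top = max(members, key=lambda s: (agg_count[s], s))
        if agg_count[top] < params.min_novel_reads:
            continue
        top_aln = next(aln for aln, seq in cluster if seq == top)
        call = _evaluate_candidate(top, top_aln, cluster, index, agg_count,
                                   agg_libs, params)
        if call.accepted:
            n += 1
            loci.append(NovelLocus(
                name=f"miR-novel-{n}", mature=top, call=call,
                total_reads=agg_count[top], libraries=set(agg_libs[top]),
            ))
        else:
            rejected.append(call)
    return _merge_loci(loci), rejected


def _evaluate_candidate(
    mature: str,
    aln: mp.Alignment,
    cluster: Sequence[tuple[mp.Alignment, str]],
    index: mp.GenomeIndex,
    agg_count: Counter,
    agg_libs: Mapping[str, set],
    params: PipelineParams,
) -> nv.NovelCall:
    """Fold both arm windows and test star-duplex / multi-library evidence."""
    from .fold import fold_rna

    best_call: nv.NovelCall | None = None
    for candidate in nv.excise_precursor(aln, index, flank=params.flank):
        candidate.fold = fold_rna(candidate.sequence)
        candidate.mfe = candidate.fold.score
        support = nv.DuplexSupport(
            mature=mature, libraries_detected=set(agg_libs[mature]),
        )
        m0 = candidate.mature_offset
        m1 = m0 + candidate.mature_len
        for other_aln, other in cluster:
            if other == mature or agg_count[other] < params.min_star_reads:
                continue
            s0, s1 = _window_coords(candidate, other_aln)
            if s0 is None:
                continue
            if nv.check_duplex(candidate, m0, m1, s0, s1,
                               tolerance=params.star_tolerance):
                support.star = other
                support.star_read_count = agg_count[other]
                support.overhang_ok = True
                break
        call = nv.call_novel(candidate, support, params.min_libraries)
        if call.rule_fired == "star_supported":
            return call
        if best_call is None or (call.accepted and not best_call.accepted):
            best_call = call
    assert best_call is not None
    return best_call


def _window_coords(candidate: nv.PrecursorCandidate,
                   aln: mp.Alignment) -> tuple[int | None, int | None]:
    """Genomic alignment -> coordinates within the excised window (strand-aware)."""
    if aln.chrom != candidate.chrom or aln.strand != candidate.strand:
        return None, None
    if aln.start < candidate.start or aln.end > candidate.end:
        return None, None
    if candidate.strand == "+":
        return aln.start - candidate.start, aln.end - candidate.start
    return candidate.end - aln.end, candidate.end - aln.start


def _merge_loci(loci: list[NovelLocus]) -> list[NovelLocus]:
    """Collapse accepted calls whose precursor windows overlap (one locus may
    surface both duplex arms as separate stacks); keep the deeper mature."""
    merged: list[NovelLocus] = []
    for locus in sorted(loci, key=lambda l: (l.call.candidate.chrom,
                                             l.call.candidate.start)):
        if merged:
            prev = merged[-1]
            same = (prev.call.candidate.chrom == locus.call.candidate.chrom
                    and prev.call.candidate.strand == locus.call.candidate.strand
                    and locus.call.candidate.start < prev.call.candidate.end)
            if same:
                if locus.total_reads > prev.total_reads:
                    merged[-1] = locus
                continue
        merged.append(locus)
    for i, locus in enumerate(merged, start=1):
        locus.name = f"miR-novel-{i}"
    return merged


def build_count_matrix(
    kept: Mapping[str, Mapping[str, int]],
    known_counts: pd.DataFrame,
    novel_loci: Sequence[NovelLocus],
    library_meta: Mapping[str, LibraryMeta],
    clean_totals: Mapping[str, int],
) -> CountMatrix:
    """miRNA x library counts over known matures plus accepted novel loci."""
    libs = list(kept)
    rows: dict[str, list[int]] = {}
    for mirna in known_counts.index:
        rows[mirna] = [int(known_counts.loc[mirna].get(lib, 0)) for lib in libs]
    for locus in novel_loci:
        rows[locus.name] = [int(kept[lib].get(locus.mature, 0)) for lib in libs]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=libs)
    meta = {
        lib: LibraryMeta(
            lib, library_meta[lib].tissue, library_meta[lib].treatment,
            library_meta[lib].replicate,
            clean_totals.get(lib, library_meta[lib].total_clean_reads),
        )
        for lib in libs
    }
    return CountMatrix(counts, meta)


def validate_targets(
    mirnas: Mapping[str, str],
    transcripts: Sequence[SequenceRecord],
    degradome_reads: Mapping[str, int],
    params: PipelineParams | None = None,
    prefix_len: int = 20,
) -> tuple[list[tg.TargetSite], list[tg.CleavageCall]]:
    """Predict target sites and confirm them against a degradome library."""
    params = params or PipelineParams()
    expanded = []
    for seq, n in degradome_reads.items():
        expanded.extend([seq] * n)
    profiles = tg.map_degradome(expanded, transcripts, prefix_len=prefix_len)
    sites: list[tg.TargetSite] = []
    calls: list[tg.CleavageCall] = []
    for name, mature in mirnas.items():
        for transcript in transcripts:
            for site in tg.scan_transcript(mature, transcript,
                                           params.penalty_params, mirna_id=name):
                sites.append(site)
                profile = profiles[transcript.id]
                try:
                    calls.append(tg.call_cleavage(site, profile))
                except tg.NoCleavageEvidence:
                    continue
    return sites, calls
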