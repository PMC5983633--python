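# Methods

This note documents the models and procedures implemented in `mirstalk`,
the defaults chosen where the field leaves room, and what the synthetic
data does and does not establish about behaviour on real libraries.

## Read cleaning

Reads are trimmed at the first exact occurrence of the first
`min_adapter_overlap` (default 8) bases of the 3′ adapter; reads in which
the adapter cannot be located are discarded, because the insert boundary
is then unknown. The cleaning rules are applied in a fixed precedence —
insert length outside 10–30 nt, 5′-adapter contamination (insert begins
with the adapter's 3′-terminal 8-mer), a single-nucleotide run longer
than 10 nt, more than 10% N — and each rejected read is tallied under the
first failing rule, so rejection tables are reproducible. Adapter
matching is exact (no mismatches): this keeps the pipeline deterministic
and errs toward discarding ambiguous reads. Quality-based trimming is
available as an optional mean-quality threshold but is off by default,
since cleaning here is defined by the rule set above. Filtering is
idempotent, and kept + rejected always equals input.

Identical raw reads are collapsed before per-sequence work wherever a
stage is a pure function of the sequence; this is an exact optimisation
chosen so that deeply sequenced libraries (10⁶ reads each in the default
design) clean and map in seconds.

## Mapping and annotation

Mapping is exact string matching of each unique read to both genome
strands through a seed index (seed length 10, the minimum read length),
verified by full-length comparison — precisely the zero-mismatch
occurrence set, as confirmed against a brute-force scan in the tests.
Coordinates are 0-based half-open internally. A multi-locus read counts
once as "mapped" in library statistics and contributes its full count to
its annotated miRNA; counts are never split across loci, matching
mature-sequence-centric miRNA counting.

A read is a known miRNA iff it is identical to a reference mature
sequence that is itself a substring of its reference hairpin. All other
mapped reads are classified by exact-substring membership in ordered
per-class reference sets, first match wins, in the fixed hierarchy
known → rRNA → tRNA → snRNA → snoRNA → scRNA → repeat → nat-siRNA →
exon → intron → novel candidate; unmapped reads are "other". The
hierarchy makes classification a total, single-valued function.

## Folding and novel miRNA calls

The built-in folder maximises a weighted nested base-pair count
(G:C = 3, A:U = 2, G:U = 1, minimum hairpin loop 3 nt) by dynamic
programming with a fixed traceback preference, so structures are pure
functions of the sequence. The score is reported as a pseudo-energy,
−(total pair weight). It ranks hairpin stability and fixes duplex
geometry but is **not** a thermodynamic free energy: when calibrated
kcal/mol values matter (e.g. MFEI reporting against published tables),
they are taken from an external MFE table or the optional ViennaRNA
plugin (`mirstalk.fold.fold_vienna`). MFEI is
(|MFE| / precursor length × 100) / GC%, with GC% as a percentage;
displayed values are rounded half-up to two decimals and full precision
is kept internally.

Candidate loci are read stacks: unannotated mapped sequences with an
aggregate count of at least `min_stack_reads` (5), clustered when within
`cluster_gap` (30 nt) on the same strand. Each cluster's deepest
sequence, if it reaches `min_novel_reads` (30) aggregate reads, is
excised in two windows (mature assumed on the 5′ or the 3′ arm;
flank 70 nt, capped at a 292-nt precursor) and folded. Star support
requires another stack in the cluster whose interval matches the
structure-implied duplex partner of the mature — the mature core's
pairing partners projected through the fold's pair table, extended by
the star's own 2-nt 3′ overhang — within ±1 nt per end. Because a true
duplex satisfies i + partner(i) = constant, the expected star interval is
derived from the **median** diagonal over the mature core, which is
robust to a few tie-broken edge pairs. The 2-nt 3′-overhang criterion is
Dicer biology, adopted as the operational definition of a star read.

A candidate is accepted if star-supported, or — when no geometrically
valid star stack exists — if its mature sequence is detected in at least
two independent libraries (replicates count as independent libraries).
Accepted calls whose windows overlap are merged to one locus (a locus can
surface both duplex arms as separate stacks), keeping the deeper mature.
The read-depth floors are expression floors, not statistical tests: they
encode the convention that a candidate miRNA must be reproducibly
sequenced, and they keep isolated background fragments from nominating
loci.

## Expression and differential expression

TPM = (miRNA reads / total clean reads) × 10⁶ per library, with "clean"
meaning all adapter-trimmed reads, per the printed formula — not only
miRNA-assigned reads. The two-group test is a transparent NB Wald test:

* per-miRNA dispersion α by method of moments, (s² − m̄)/m̄² pooled
  across the two groups, floored at 10⁻⁸;
* group abundance q = depth-weighted mean TPM; its variance by the delta
  method under Var(count) = μ + αμ²;
* Wald statistic on log((q_B + c)/(q_A + c)) with pseudocount c = 1 TPM
  (declared in output metadata), referred to the standard normal;
* Benjamini–Hochberg adjustment (the standard reading of "adjusted
  p-value" in this literature; delegated to statsmodels and checked
  against the textbook step-up formula in the tests);
* significance = |log₂FC| ≥ 1 and adjusted p ≤ 0.05.

The test is symmetric (swapping groups negates every log₂FC), drops
miRNAs with zero counts in both groups, and requires ≥ 2 libraries per
group. On the default simulation (20 planted 4-fold changes, NB
dispersion 0.05, n = 3 per group, depth 10⁶) it reaches sensitivity ≥ 0.9
at observed FDR ≤ 0.1, and under a 1000-miRNA null simulation the
fraction of adjusted p ≤ 0.05 stays below 5% — both checked in
`tests/test_acceptance.py`. qPCR follow-up uses
2^−[(Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control].

## Target prediction and degradome classification

Target scoring is ungapped and antiparallel: miRNA position i (1-based
from the 5′ end) faces site position L − i + 1. A G:U wobble costs 0.5,
any other mismatch 0.5, doubled when the miRNA position lies in 2–13;
windows with total ≤ 4 points pass (the cutoff is inclusive, the maximal
admissible score). Both penalties and the cutoff are parameters of
`PenaltyParams`. Bulged or gapped sites are out of scope: the published
scheme defines penalties only for paired positions, and inventing gap
penalties would change the statistic.

Degradome reads are matched by the exact occurrence of their first 20 nt
(configurable) — the informative 5′ end of the cleavage fragment — and
every match increments the 5′-end counter at the match start;
multi-transcript hits increment each transcript. The expected cleavage
position of a target site is the transcript coordinate opposite miRNA
position 10. Categories are assigned with an explicit precedence: a
single read at the site → category 5; otherwise unique transcript
maximum → 1; tied maximum → 2; at or above the median → 3; below it → 4.
Category 5 is tested first because a transcript whose only signal is one
read at the site would otherwise be ambiguous between 1 and 5; the median
is computed over positions carrying at least one read. Both choices are
visible in the API and fixed in the tests.

## Synthetic data: what it emulates and what it does not

The generator's default is the study design it emulates: 18 libraries
(stem/root × control, 1-day, 4-day treatment × 3 replicates) at 10⁶
reads each; insert lengths peaking at 24 nt then 21 nt; NB counts with
dispersion 0.05; 20 known and 20 novel planted hairpins plus 10
single-library decoys; 20 planted 4-fold (|log₂FC| = 2) expression
changes; star reads at 10% of mature counts; 2% of reads as random
genomic background (modelling unannotated degradation; planted locus
footprints are excluded from background sampling so a decoy's
single-library truth label stays true); sequencing errors off by default
so recovery can be scored exactly. Planted precursors are
mature + 8-nt A-loop + exact-complement star with 2-nt 3′ overhangs, on
either strand, with GC-rich matures (≈55%) and a 50% 5′-U bias. The
degradome library plants five sites per category with profiles that
realise each category by construction, with no background noise by
default (noise would move the transcript median and silently change
intended categories 3/4).

All emitters draw from one seed through named substreams, so outputs are
byte-identical under a fixed seed and adding an emitter does not perturb
the others.

What passing recovery tests on these data shows: the pipeline's rules
are implemented correctly and the chain is lossless at zero error rate.
What it does not show: robustness to adapter variants, quality decay,
PCR duplication, isomiR heterogeneity, multi-branch precursors, or
repeat-rich genomes — real libraries have all of these, and the planted
hairpins are deliberately clean two-arm stems.

## Numerical and engineering choices

* Canonical internal alphabet is DNA (T); U is converted on input and
  report tables render miRNA sequences with U. GC% excludes N from both
  numerator and denominator.
* Folding ties are broken by a fixed traceback order (i unpaired, j
  unpaired, pair i:j, leftmost bifurcation), making structures
  deterministic; the DP equals exhaustive enumeration on all tested
  sequences ≤ 18 nt.
* Degenerate inputs fail loudly: empty sequences, GC% = 0 in MFEI,
  zero-depth TPM, overlapping DE groups, and cleavage positions without
  reads all raise typed errors rather than returning silent defaults.
* The end-to-end default run (18 × 10⁶ reads) completes in well under a
  minute and ~0.5 GB on one core because identical reads are collapsed
  before per-sequence work; problem sizes in the tests were chosen to
  exercise the same code paths at full design scale.

## Known limitations

* The pseudo-energy folder cannot reproduce published kcal/mol MFE
  values; it is a ranking and geometry device (by design — see above).
* Exact matching everywhere (adapters, mapping, annotation) trades
  sensitivity on error-containing reads for determinism; real libraries
  lose a few percent of reads that a mismatch-tolerant aligner would
  place.
* The NB Wald test with method-of-moments dispersion is anti-conservative
  for very low counts at n = 3; the |log₂FC| ≥ 1 requirement in the
  significance rule is what keeps the realised FDR low in that regime.
* Venn-region summaries are computed for up to three comparisons, the
  report shape used in practice.
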