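"""miRNA expression: TPM normalization, differential expression, qPCR ratios.

Counts are normalized per library as TPM = (miRNA reads / total clean
reads) x 1e6.  Differential expression between two groups of libraries is
a transparent negative-binomial Wald test: per-miRNA dispersion is
estimated by method of moments pooled across the two groups (floored at
1e-8), the group abundance is the depth-weighted mean TPM, and the Wald
statistic on the log abundance ratio is referred to the standard normal,
as is conventional for NB Wald tests.  Significance uses the screening rule
|log2 fold-change| >= 1 and Benjamini-Hochberg adjusted p <= 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2FC_THRESHOLD = 1.0
PADJ_THRESHOLD = 0.05
PSEUDOCOUNT_TPM = 1.0
DISPERSION_FLOOR = 1e-8


@dataclass
class LibraryMeta:
    library_id: str
    tissue: str  # leaf | stem | root
    treatment: str  # C | S | L
    replicate: int
    total_clean_reads: int


@dataclass
class CountMatrix:
    """miRNA x library raw counts plus library metadata."""

    counts: pd.DataFrame  # rows: miRNA ids, columns: library ids
    libraries: dict[str, LibraryMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.libraries)
        if missing:
            raise ValueError(f"libraries without metadata: {sorted(missing)}")

    def total_clean(self, library_id: str) -> int:
        return self.libraries[library_id].total_clean_reads

    def tpm_matrix(self) -> pd.DataFrame:
        totals = np.array([self.total_clean(c) for c in self.counts.columns], float)
        if (totals <= 0).any():
            raise ValueError("every library needs total_clean_reads > 0")
        return self.counts / totals * 1e6


def tpm(count: float, total_clean: int) -> float:
    """Reads-per-million normalization of a single miRNA count."""
    if total_clean <= 0:
        raise ValueError("total clean reads must be positive")
    return count / total_clean * 1e6


@dataclass
class DEResult:
    mirna: str
    comparison: str
    log2fc: float
    mean_a: float  # group mean TPM
    mean_b: float
    p: float
    padj: float

    @property
    def significant(self) -> bool:
        return abs(self.log2fc) >= LOG2FC_THRESHOLD and self.padj <= PADJ_THRESHOLD

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def _pooled_dispersion(counts: np.ndarray, groups: Sequence[np.ndarray]) -> np.ndarray:
    """Method-of-moments NB dispersion per miRNA, pooled across groups."""
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    for cols in groups:
        sub = counts[:, cols]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        num += var - mean
        den += mean ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, DISPERSION_FLOOR)


def de_test(
    matrix: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    comparison: str | None = None,
    pseudocount: float = PSEUDOCOUNT_TPM,
) -> list[DEResult]:
    """Negative-binomial Wald test of group B vs group A.

    log2FC = log2((mean TPM_B + c) / (mean TPM_A + c)) with pseudocount
    ``c``; p-values come from the Wald statistic on the log abundance
    ratio with delta-method variance under the NB model.  miRNAs with zero
    counts across both groups are dropped.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two libraries")
    comparison = comparison or f"{'+'.join(group_b)} vs {'+'.join(group_a)}"

    cols = group_a + group_b
    counts = matrix.counts[cols].to_numpy(dtype=float)
    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    mirnas = matrix.counts.index[keep]
    depths = np.array([matrix.total_clean(c) for c in cols], dtype=float)
    ia = np.arange(len(group_a))
    ib = np.arange(len(group_a), len(cols))

    alpha = _pooled_dispersion(counts, [ia, ib])

    def group_stats(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = depths[idx]
        # depth-weighted mean TPM and its NB delta-method variance
        q = counts[:, idx].sum(axis=1) / d.sum() * 1e6
        mu = q[:, None] * d[None, :] / 1e6  # expected counts per library
        var_counts = mu + alpha[:, None] * mu ** 2
        var_q = var_counts.sum(axis=1) * (1e6 / d.sum()) ** 2
        return q, var_q

    qa, var_a = group_stats(ia)
    qb, var_b = group_stats(ib)

    log2fc = np.log2((qb + pseudocount) / (qa + pseudocount))
    log_ratio = np.log(qb + pseudocount) - np.log(qa + pseudocount)
    se = np.sqrt(var_a / (qa + pseudocount) ** 2 + var_b / (qb + pseudocount) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log_ratio / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    padj = bh_adjust(p)

    return [
        DEResult(str(m), comparison, float(fc), float(a), float(b),
                 float(pv), float(pa))
        for m, fc, a, b, pv, pa in zip(mirnas, log2fc, qa, qb, p, padj)
    ]


def de_table(results: Iterable[DEResult]) -> pd.DataFrame:
    rows = [
        {
            "miRNA": r.mirna, "comparison": r.comparison, "log2FC": r.log2fc,
            "p": r.p, "padj": r.padj, "significant": r.significant,
            "direction": r.direction,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


@dataclass
class ComparisonSummary:
    up_down: dict[str, tuple[int, int]]
    venn: dict[frozenset, int]


def comparison_summary(
    results_by_comparison: Mapping[str, Sequence[DEResult]]
) -> ComparisonSummary:
    """Up/down tallies per comparison and exclusive Venn-region counts of the
    significant sets (all 2^k - 1 regions for k comparisons)."""
    sig_sets = {
        label: {r.mirna for r in results if r.significant}
        for label, results in results_by_comparison.items()
    }
    up_down = {}
    for label, results in results_by_comparison.items():
        up = sum(1 for r in results if r.significant and r.direction == "up")
        down = sum(1 for r in results if r.significant and r.direction == "down")
        up_down[label] = (up, down)

    labels = list(sig_sets)
    venn: dict[frozenset, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(sig_sets[l] for l in combo))
            outside = set().union(*(sig_sets[l] for l in labels if l not in combo)) \
                if len(combo) < len(labels) else set()
            venn[frozenset(combo)] = len(inside - outside)
    return ComparisonSummary(up_down, venn)


@dataclass
class QPCRSample:
    """Ct values for the 2^-ddCt relative-expression calculation."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        for value in (self.ct_target_treated, self.ct_ref_treated,
                      self.ct_target_control, self.ct_ref_control):
            if value is None or not math.isfinite(value) or value <= 0:
                raise ValueError("all four Ct values must be positive and finite")


def ddct(sample: QPCRSample) -> float:
    """Relative expression by the 2^-ddCt method (treated vs control,
    target normalized to the reference gene)."""
    delta_treated = sample.ct_target_treated - sample.ct_ref_treated
    delta_control = sample.ct_target_control - sample.ct_ref_control
    return 2.0 ** -(delta_treated - delta_control)
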