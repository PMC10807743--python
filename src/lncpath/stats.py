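"""Shared statistical kernel: Fisher enrichment, rank correlations, Wilcoxon
tests, Bonferroni correction and genomic nearest-feature distances.

These are the primitives behind every enrichment analysis in the pipeline:
2x2 Fisher tests with sample odds ratios, Spearman/Pearson correlation of
expression profiles, rank-sum and paired signed-rank comparisons, and gap
distances between gene spans and interval tracks (e.g. H3K27ac marks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats

__all__ = [
    "EnrichmentResult",
    "CorrelationResult",
    "fisher_exact",
    "pearson",
    "spearman",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank_paired",
    "bonferroni",
    "nearest_feature_distance",
]


@dataclass
class EnrichmentResult:
    """A 2x2 enrichment test outcome.

    ``odds_ratio`` is the sample (unconditional) odds ratio a*d/(b*c),
    with 0/0 -> NaN and x/0 -> inf.  ``p_adjusted`` is filled in by callers
    that correct over a family of tests.
    """

    table: np.ndarray
    odds_ratio: float
    p_value: float
    method: str = "fisher"
    p_adjusted: float | None = None
    label: tuple = field(default_factory=tuple)

    @property
    def nominal_significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def adjusted_significant(self) -> bool:
        return self.p_adjusted is not None and self.p_adjusted < 0.05


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    method: str
    n: int


def _sample_odds_ratio(table: np.ndarray) -> float:
    a, b = table[0]
    c, d = table[1]
    num = float(a) * float(d)
    den = float(b) * float(c)
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def fisher_exact(table, conditional: bool = False) -> EnrichmentResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    The two-sided p sums hypergeometric probabilities of tables no more
    probable than the observed one (R's convention).  By default the sample
    odds ratio is reported; ``conditional=True`` reports the conditional
    maximum-likelihood odds ratio instead (what R's ``fisher.test`` prints).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if t.sum() <= 0:
        raise ValueError("table grand total must be positive")
    ti = t.astype(np.int64)
    if not np.array_equal(ti, t):
        raise ValueError("table entries must be integers")
    _, p = scipy.stats.fisher_exact(ti, alternative="two-sided")
    if conditional:
        orat = float(scipy.stats.contingency.odds_ratio(ti).statistic)
    else:
        orat = _sample_odds_ratio(ti)
    return EnrichmentResult(table=ti, odds_ratio=orat, p_value=float(p))


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return x, y


def pearson(x, y) -> CorrelationResult:
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, "pearson", len(x))
    r, p = scipy.stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), "pearson", len(x))


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson on average-ranked data, p from the
    t approximation t = r*sqrt((n-2)/(1-r^2))."""
    x, y = _check_xy(x, y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(math.nan, math.nan, "spearman", len(x))
    r, p = scipy.stats.spearmanr(x, y)
    return CorrelationResult(float(r), float(p), "spearman", len(x))


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon (Mann-Whitney) rank-sum p-value.

    Exact distribution when both groups have <= 25 tie-free observations;
    otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(a), len(b)) <= 25 and not ties) else "asymptotic"
    return float(
        scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def wilcoxon_signed_rank_paired(a, b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Exact for <= 20 nonzero tie-free differences, else normal approximation.
    All-zero differences are an error (no information about a shift).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        raise ValueError("all paired differences are zero")
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 20 and not ties) else "approx"
    return float(
        scipy.stats.wilcoxon(a, b, alternative="two-sided", method=method).pvalue
    )


def bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: min(1, p*m)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def interval_gap(start1: int, end1: int, start2: int, end2: int) -> int:
    """Bases strictly between two 1-based closed intervals; 0 if they
    overlap or touch."""
    if start1 > start2:
        start1, end1, start2, end2 = start2, end2, start1, end1
    return max(0, start2 - end1 - 1)


def nearest_feature_distance(genes, features, anchor: str = "span") -> dict[str, float]:
    """Distance from each gene to its nearest same-chromosome feature.

    ``genes`` is an iterable of GeneRecord; ``features`` of GenomicInterval.
    Distance is the number of bases strictly between the gene span (or TSS
    with ``anchor='tss'``) and the feature, 0 when they overlap or touch,
    inf when the gene's chromosome carries no feature.
    """
    features = list(features)
    if not features:
        raise ValueError("feature list is empty")
    if anchor not in ("span", "tss"):
        raise ValueError("anchor must be 'span' or 'tss'")
    by_chrom: dict[str, list] = {}
    for f in features:
        by_chrom.setdefault(f.chromosome, []).append(f)
    out: dict[str, float] = {}
    for g in genes:
        span = g.span
        if anchor == "tss":
            tss = span.start if span.strand != "-" else span.end
            gs = ge = tss
        else:
            gs, ge = span.start, span.end
        best = math.inf
        for f in by_chrom.get(span.chromosome, ()):
            best = min(best, interval_gap(gs, ge, f.start, f.end))
            if best == 0:
                break
        out[g.gene_id] = best
    return out
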