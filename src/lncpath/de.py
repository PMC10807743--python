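"""Count normalization and differential expression.

Counts are normalized to log2 counts-per-million; per-gene differential
expression between two sample groups is an ordinary least-squares fit of
log-CPM on a group indicator plus covariates, with a two-sided t-test on
the group coefficient and Benjamini-Hochberg correction across genes.
A gene is called differentially expressed when |logFC| >= 1 and
FDR <= 0.05 (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .stats import fisher_exact, EnrichmentResult, bonferroni as _bonferroni

__all__ = [
    "ExpressionMatrix",
    "log_cpm",
    "bh_adjust",
    "differential_expression",
    "shared_de_overlap",
    "pairwise_shared_de",
    "expression_filter",
]

DEFAULT_LFC = 1.0
DEFAULT_FDR = 0.05


@dataclass
class ExpressionMatrix:
    """Gene x sample integer counts plus per-sample metadata.

    ``counts``: DataFrame indexed by gene_id with sample_id columns.
    ``sample_metadata``: DataFrame indexed by sample_id; must carry a
    ``condition`` column (the declared condition vocabulary) and may carry
    a ``group`` column plus arbitrary covariates.
    """

    counts: pd.DataFrame
    sample_metadata: pd.DataFrame

    def __post_init__(self):
        if list(self.counts.columns) != list(self.sample_metadata.index):
            raise ValueError("counts columns and metadata index must match")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if "condition" not in self.sample_metadata.columns:
            raise ValueError("sample_metadata must have a 'condition' column")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str, column: str = "group") -> list[str]:
        meta = self.sample_metadata
        col = column if column in meta.columns else "condition"
        return list(meta.index[meta[col] == group])


def log_cpm(matrix: ExpressionMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million: log2((c + p) / (lib + 2p) * 1e6)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    counts = matrix.counts.astype(float)
    lib = counts.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero)}")
    return np.log2((counts + pseudocount) / (lib + 2 * pseudocount) * 1e6)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _design_matrix(meta: pd.DataFrame, group_samples, other_samples, covariates):
    samples = list(group_samples) + list(other_samples)
    indicator = np.r_[np.ones(len(group_samples)), np.zeros(len(other_samples))]
    cols = [np.ones(len(samples)), indicator]
    for cov in covariates:
        v = meta.loc[samples, cov]
        if v.dtype.kind in "biufc":
            cols.append(v.to_numpy(dtype=float))
        else:
            dummies = pd.get_dummies(v, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient (covariate collinear with group?)")
    return samples, X


def differential_expression(
    matrix: ExpressionMatrix,
    contrast: tuple[str, str],
    covariates: list[str] | None = None,
    group_column: str = "group",
    lfc_threshold: float = DEFAULT_LFC,
    fdr_threshold: float = DEFAULT_FDR,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene OLS differential expression for groupA vs groupB.

    logFC is the coefficient of the groupA indicator on log2-CPM (positive =
    higher in groupA); p from a two-sided t-test on that coefficient; FDR by
    Benjamini-Hochberg across genes.  Returns a DE table with columns
    gene_id, contrast, logFC, pvalue, fdr, is_de, direction.
    """
    covariates = covariates or []
    group_a, group_b = contrast
    sa = matrix.samples_in_group(group_a, group_column)
    sb = matrix.samples_in_group(group_b, group_column)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError(
            f"need >= 2 samples per group, got {len(sa)} ({group_a}) and {len(sb)} ({group_b})"
        )
    samples, X = _design_matrix(matrix.sample_metadata, sa, sb, covariates)
    n, p = X.shape
    if n <= p:
        raise ValueError("fewer residual degrees of freedom than parameters")
    logcpm = log_cpm(matrix, pseudocount=pseudocount)
    Y = logcpm[samples].to_numpy().T  # samples x genes
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)  # p x genes
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0))
    lfc = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    pvals = 2 * scipy.stats.t.sf(np.abs(t), dof)
    fdr = bh_adjust(pvals)
    is_de = (np.abs(lfc) >= lfc_threshold) & (fdr <= fdr_threshold)
    direction = np.where(lfc > 0, "up", "down")
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "contrast": f"{group_a}:{group_b}",
            "logFC": lfc,
            "pvalue": pvals,
            "fdr": fdr,
            "is_de": is_de,
            "direction": direction,
        }
    )


def de_gene_set(table: pd.DataFrame) -> set[str]:
    return set(table.loc[table["is_de"], "gene_id"])


def shared_de_overlap(table_a: pd.DataFrame, table_b: pd.DataFrame, universe) -> EnrichmentResult:
    """Fisher test for overlap of the two DE gene sets over a gene universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    a = de_gene_set(table_a) & universe
    b = de_gene_set(table_b) & universe
    if not (de_gene_set(table_a) <= universe and de_gene_set(table_b) <= universe):
        raise ValueError("universe must contain all DE genes of both tables")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    res = fisher_exact([[n11, n10], [n01, n00]])
    res.label = (str(table_a["contrast"].iloc[0]), str(table_b["contrast"].iloc[0]))
    return res


def pairwise_shared_de(tables: list[pd.DataFrame], universe) -> list[EnrichmentResult]:
    """All-pairs shared-DE Fisher tests with Bonferroni over the pairs."""
    results = []
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            results.append(shared_de_overlap(tables[i], tables[j], universe))
    adj = _bonferroni([r.p_value for r in results]) if results else []
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
    return results


def expression_filter(
    matrix: ExpressionMatrix, min_mean_cpm: float = 1.0, by: str = "condition"
) -> list[str]:
    """Genes whose mean CPM reaches ``min_mean_cpm`` in at least one
    condition group (an 'expressed somewhere' filter)."""
    counts = matrix.counts.astype(float)
    cpm = counts / counts.sum(axis=0) * 1e6
    keep = pd.Series(False, index=counts.index)
    for _, samples in matrix.sample_metadata.groupby(by).groups.items():
        keep |= cpm[list(samples)].mean(axis=1) >= min_mean_cpm
    return list(keep.index[keep])
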