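"""Expression normalization, expression binning, and the
acetylation-expression association.

Microarray-style intensities are quantile-normalized so every sample shares
one empirical distribution, genes are ranked by mean normalized expression
into equally sized bins (deciles by default), and the association between
expression and promoter acetylation is summarized by Spearman's rank
correlation together with per-decile mean metagene profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTable",
    "quantile_normalize",
    "bin_by_expression",
    "expression_acetylation_association",
    "AssociationResult",
]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a genes x samples matrix.

    After normalization every column's sorted values equal the rank-wise mean
    of the input columns' sorted values; tied entries within a column receive
    the mean of their tied quantiles. Idempotent. A single-column input is
    returned unchanged with a warning.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile_normalize: missing values not allowed")
    if matrix.shape[1] < 2:
        logger.warning("quantile_normalize: single sample, returning input unchanged")
        return matrix.copy()
    X = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")  # 1-based, .5 on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (mean_sorted[lo] + mean_sorted[hi])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def bin_by_expression(mean_expression: pd.Series, n_bins: int = 10) -> pd.Series:
    """Assign each gene an expression bin 1..n_bins (1 = lowest expressed).

    Genes are sorted ascending by mean expression (ties broken by gene id),
    split into contiguous bins of equal size floor(n/n_bins); remainder genes
    go to the highest bin.
    """
    n = len(mean_expression)
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds number of genes {n}")
    order = sorted(mean_expression.index, key=lambda g: (mean_expression[g], g))
    base = n // n_bins
    labels = pd.Series(n_bins, index=pd.Index(order), dtype=int)
    for b in range(1, n_bins):
        labels.iloc[(b - 1) * base : b * base] = b
    return labels.reindex(mean_expression.index)


class ExpressionTable:
    """Quantile-normalized per-gene expression with bin labels.

    Parameters
    ----------
    intensities:
        genes x samples DataFrame of raw intensities.
    log2_transformed:
        if False, log2(x + 1) is applied before normalization.
    n_bins:
        number of equally sized expression bins.
    expressed_quantile:
        genes whose mean normalized expression exceeds this quantile of all
        genes are flagged as expressed (default: 20th percentile, i.e. the
        bottom fifth of genes is treated as unexpressed).
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        log2_transformed: bool = True,
        n_bins: int = 10,
        expressed_quantile: float = 0.2,
        normalize: bool = True,
    ) -> None:
        values = intensities.astype(float)
        if not log2_transformed:
            values = np.log2(values + 1.0)
        self.values = quantile_normalize(values) if normalize and values.shape[1] >= 2 else values
        self.n_bins = n_bins
        self.expressed_quantile = expressed_quantile

    @property
    def mean_expression(self) -> pd.Series:
        return self.values.mean(axis=1)

    @property
    def decile(self) -> pd.Series:
        return bin_by_expression(self.mean_expression, self.n_bins)

    @property
    def expressed(self) -> pd.Series:
        mean = self.mean_expression
        return mean > mean.quantile(self.expressed_quantile)

    @property
    def rank(self) -> pd.Series:
        """Dense 1..n expression rank, ascending, ties broken by gene id."""
        order = sorted(self.values.index, key=lambda g: (self.mean_expression[g], g))
        return pd.Series(np.arange(1, len(order) + 1), index=pd.Index(order)).reindex(
            self.values.index
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_expression": self.mean_expression,
                "decile": self.decile,
                "expressed": self.expressed,
            }
        )

    @classmethod
    def read_tsv(cls, path, **kwargs) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, **kwargs)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class AssociationResult:
    """Spearman association between expression and promoter acetylation."""

    rho_promoter: float
    rho_window: float
    n_genes: int
    decile_profiles: pd.DataFrame | None  # rows = decile, cols = profile bins


def expression_acetylation_association(
    scores: pd.DataFrame,
    table: ExpressionTable,
    profile_matrix: pd.DataFrame | None = None,
) -> AssociationResult:
    """Correlate per-gene acetylation scores with expression.

    ``scores`` is the gene_scores frame (promoter_reads, window_score).
    ``profile_matrix`` (optional, genes x bins) yields per-decile mean
    profiles. Zero variance in either variable gives rho = NaN (undefined).
    """
    common = scores.index.intersection(table.values.index)
    if len(common) < 3:
        raise ValueError("need >= 3 genes with both score and expression")
    expr = table.mean_expression.loc[common]

    def rho(col: str) -> float:
        y = scores.loc[common, col]
        if expr.nunique() <= 1 or y.nunique() <= 1:
            return float("nan")
        return float(stats.spearmanr(expr, y).statistic)

    decile_profiles = None
    if profile_matrix is not None:
        dec = table.decile.loc[profile_matrix.index.intersection(common)]
        decile_profiles = profile_matrix.loc[dec.index].groupby(dec).mean()
        decile_profiles.index.name = "decile"

    return AssociationResult(
        rho_promoter=rho("promoter_reads"),
        rho_window=rho("window_score"),
        n_genes=len(common),
        decile_profiles=decile_profiles,
    )
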