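"""k-means clustering of TSS acetylation profiles and contribution tables.

Each gene's binned +/-2 kb depth vector is (by default) rescaled to unit sum
so that clusters capture profile *shape* — promoter-peaked, gene-body-peaked
or unenriched — rather than amplitude. Cluster labels are renumbered by
descending centroid peak offset so that label 1 is the most downstream
(gene-body) cluster, making reports stable across seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .coverage import GeneDepths, ReadSet, bin_depth, per_gene_depth
from .genome_model import GeneAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "profile_matrix",
    "kmeans_profiles",
    "contribution_crosstab",
    "ClusterAssignment",
]


def profile_matrix(
    reads: ReadSet,
    genes: Sequence[GeneAnnotation],
    window: int = 2000,
    bin_bp: int = 10,
    scale: str = "unit_sum",
    depths: GeneDepths | None = None,
) -> pd.DataFrame:
    """Per-gene binned depth vectors (genes x bins), strand-oriented.

    ``scale="unit_sum"`` rescales each nonzero row to sum 1; ``scale="raw"``
    keeps mean depth. Columns are the left edges of the offset bins.
    """
    if window % bin_bp != 0:
        raise ValueError("window must be a multiple of bin_bp")
    if depths is None:
        depths = per_gene_depth(reads, genes, window)
    elif depths.window < window:
        raise ValueError("supplied depths narrower than requested window")
    offsets = np.arange(-window, window, bin_bp)
    rows = {}
    off = depths.window - window  # crop wider depth arrays symmetrically
    for g in genes:
        d = depths.depth[g.gene_id]
        if off:
            d = d[off:-off]
        rows[g.gene_id] = bin_depth(d, bin_bp)
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=offsets)
    if scale == "unit_sum":
        sums = mat.sum(axis=1)
        nz = sums > 0
        mat.loc[nz] = mat.loc[nz].div(sums[nz], axis=0)
    elif scale != "raw":
        raise ValueError(f"unknown scale mode: {scale}")
    return mat


@dataclass
class ClusterAssignment:
    """Seeded k-means result over gene profiles.

    ``labels`` maps gene_id -> cluster 1..k; ``centroids`` rows are indexed
    by the same labels; ``semantic`` gives a post-hoc description of each
    cluster ("promoter", "gene_body" or "unenriched") from its centroid peak
    — reported only, never used in computation.
    """

    labels: pd.Series
    centroids: pd.DataFrame
    inertia: float

    @property
    def k(self) -> int:
        return len(self.centroids)

    @property
    def semantic(self) -> dict[int, str]:
        out = {}
        grand = self.centroids.to_numpy().mean()
        for label, row in self.centroids.iterrows():
            peak_off = float(row.idxmax())
            if row.max() < 1.5 * grand:
                out[int(label)] = "unenriched"
            elif peak_off >= 0:
                out[int(label)] = "gene_body"
            else:
                out[int(label)] = "promoter"
        return out


def kmeans_profiles(
    matrix: pd.DataFrame, k: int = 5, seed: int = 0, restarts: int = 10
) -> ClusterAssignment:
    """Cluster profile rows with seeded k-means++ (best of ``restarts`` runs).

    Deterministic given ``seed``. Clusters are relabeled 1..k by descending
    centroid peak offset (ties by descending peak height) for stable
    reporting.
    """
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds number of profiles {len(matrix)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts, random_state=seed)
    raw = km.fit_predict(matrix.to_numpy())
    try:
        cols = matrix.columns.to_numpy(dtype=float)
    except (TypeError, ValueError):
        cols = np.arange(matrix.shape[1], dtype=float)  # non-offset columns
    order = sorted(
        range(k),
        key=lambda c: (
            float(cols[np.argmax(km.cluster_centers_[c])]),
            float(km.cluster_centers_[c].max()),
        ),
        reverse=True,
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=matrix.index, dtype=int)
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=range(1, k + 1), columns=matrix.columns
    )
    return ClusterAssignment(labels=labels, centroids=centroids, inertia=float(km.inertia_))


def contribution_crosstab(
    assignment: ClusterAssignment, strata: Mapping[str, object] | pd.Series
) -> pd.DataFrame:
    """Row-normalized cluster fractions per stratum.

    Rows are stratification levels (e.g. expression deciles or TFBS
    categories), columns clusters 1..k; each row sums to 1. Genes without a
    stratum are dropped with a log message; empty strata are omitted.
    """
    strata = pd.Series(strata)
    common = assignment.labels.index.intersection(strata.index)
    missing = len(assignment.labels) - len(common)
    if missing:
        logger.info("contribution_crosstab: %d genes lack a stratum, dropped", missing)
    tab = pd.crosstab(strata.loc[common], assignment.labels.loc[common], normalize="index")
    tab = tab.reindex(columns=range(1, assignment.k + 1), fill_value=0.0)
    tab.columns.name = "cluster"
    return tab
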