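"""Positional interplay between TFBS and promoter acetylation.

Three views of how transcription-factor binding sites condition acetylation
around the TSS:

* per-position percentage of expressed genes acetylated, split by whether a
  TFBS is annotated at that position (plus the unexpressed-gene curve);
* metagene profiles conditioned on TFBS location classes (site at -500,
  -800, -1100 bp; no site proximal to the TSS) against an all-genes
  baseline;
* an exhaustive categorization of genes by promoter TFBS content relative
  to a proximal cutoff (150 bp by default).

"Acetylated at offset x" means base-level depth >= ``min_depth`` at x. The
per-position percentages here are true bounded proportions in [0, 100]; a
multi-site numerator that can exceed 100% is deliberately not used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import GeneDepths, TssProfile, bin_depth
from .genome_model import GeneAnnotation, TfbsSite

logger = logging.getLogger(__name__)

__all__ = [
    "acetylated_at",
    "positional_curves",
    "smooth_running_median",
    "conditional_profiles",
    "categorize_tfbs",
    "PositionalCurve",
    "TFBS_CATEGORIES",
]

TFBS_CATEGORIES = (
    "NO_TFBS_IN_PROMOTER",
    "NONE_BEYOND_150",
    "ONE_BEYOND_150",
    "MULTI_BEYOND_150",
)


def acetylated_at(
    depths: GeneDepths, gene_id: str, offset: int, min_depth: float = 1
) -> bool:
    """True iff base-level depth at the TSS-relative offset >= min_depth."""
    return depths.at(gene_id, offset) >= min_depth


@dataclass
class PositionalCurve:
    """Percent of genes acetylated per promoter position, by TFBS status.

    Values are NaN where the denominator (genes with/without a site at that
    position) is empty. ``positions`` are TSS-relative offsets (negative =
    upstream).
    """

    positions: np.ndarray
    with_tfbs_pct: np.ndarray
    without_tfbs_pct: np.ndarray
    unexpressed_pct: np.ndarray

    def smoothed(self, width: int = 10) -> "PositionalCurve":
        return PositionalCurve(
            positions=self.positions,
            with_tfbs_pct=smooth_running_median(self.with_tfbs_pct, width),
            without_tfbs_pct=smooth_running_median(self.without_tfbs_pct, width),
            unexpressed_pct=smooth_running_median(self.unexpressed_pct, width),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.positions,
                "with_tfbs_pct": self.with_tfbs_pct,
                "without_tfbs_pct": self.without_tfbs_pct,
                "unexpressed_pct": self.unexpressed_pct,
            }
        )


def _sites_by_gene(tfbs: Sequence[TfbsSite]) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for s in tfbs:
        out.setdefault(s.gene_id, []).append(s.offset)
    return out


def positional_curves(
    genes: Sequence[GeneAnnotation],
    depths: GeneDepths,
    tfbs: Sequence[TfbsSite],
    expressed: Mapping[str, bool] | pd.Series,
    promoter_bp: int = 2000,
    step_bp: int = 10,
    tolerance_bp: int | None = None,
    min_depth: float = 1,
) -> PositionalCurve:
    """Percent of genes acetylated at each upstream position, by TFBS status.

    At each position x in {-promoter_bp, ..., -step_bp}:

    * ``with_tfbs_pct``  = 100 * |expressed genes with a site within
      tolerance of x that are acetylated at x| / |expressed genes with a
      site at x|;
    * ``without_tfbs_pct`` analogous over expressed genes lacking a site at x;
    * ``unexpressed_pct`` over unexpressed genes (regardless of TFBS).

    ``tolerance_bp`` defaults to half the step width.
    """
    if depths.window < promoter_bp:
        raise ValueError("depth window narrower than promoter scan")
    if tolerance_bp is None:
        tolerance_bp = step_bp // 2
    positions = np.arange(-promoter_bp, 0, step_bp)
    sites = _sites_by_gene(tfbs)
    expressed = pd.Series(expressed)

    gene_ids = [g.gene_id for g in genes]
    expr_ids = [g for g in gene_ids if bool(expressed.get(g, False))]
    unexpr_ids = [g for g in gene_ids if not bool(expressed.get(g, False))]

    with_pct = np.full(len(positions), np.nan)
    without_pct = np.full(len(positions), np.nan)
    unexpr_pct = np.full(len(positions), np.nan)

    # precompute per-gene acetylation indicator over scan positions
    def acet_vec(ids: list[str]) -> np.ndarray:
        idx = positions + depths.window
        return np.array(
            [depths.depth[g][idx] >= min_depth for g in ids], dtype=bool
        ) if ids else np.zeros((0, len(positions)), dtype=bool)

    expr_acet = acet_vec(expr_ids)
    unexpr_acet = acet_vec(unexpr_ids)

    has_site = np.zeros((len(expr_ids), len(positions)), dtype=bool)
    for i, g in enumerate(expr_ids):
        for off in sites.get(g, ()):
            lo = np.searchsorted(positions, off - tolerance_bp, side="left")
            hi = np.searchsorted(positions, off + tolerance_bp, side="right")
            has_site[i, lo:hi] = True

    for j in range(len(positions)):
        w = has_site[:, j]
        if w.any():
            with_pct[j] = 100.0 * expr_acet[w, j].mean()
        if (~w).any() and len(expr_ids):
            without_pct[j] = 100.0 * expr_acet[~w, j].mean()
        if len(unexpr_ids):
            unexpr_pct[j] = 100.0 * unexpr_acet[:, j].mean()

    return PositionalCurve(positions, with_pct, without_pct, unexpr_pct)


def smooth_running_median(values: np.ndarray, width: int = 10) -> np.ndarray:
    """Centered running median; shrinking windows at the edges, NaN skipped.

    The window at index i spans indices within width // 2 of i. A position
    whose window is all-NaN stays NaN.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    values = np.asarray(values, dtype=float)
    half = width // 2
    out = np.full_like(values, np.nan)
    for i in range(len(values)):
        win = values[max(0, i - half) : i + half + 1]
        win = win[~np.isnan(win)]
        if len(win):
            out[i] = np.median(win)
    return out


def conditional_profiles(
    genes: Sequence[GeneAnnotation],
    depths: GeneDepths,
    tfbs: Sequence[TfbsSite],
    anchors: Sequence[int] = (-500, -800, -1100),
    tolerance_bp: int = 25,
    no_tfbs_within: int = 100,
    window: int = 2000,
    bin_bp: int = 10,
) -> dict[str, TssProfile]:
    """Metagene profiles for TFBS-defined gene classes plus an all-genes baseline.

    Classes: for each anchor offset, genes with >= 1 site within
    ``tolerance_bp`` of the anchor ("tfbs_at_-800" etc.); plus
    "no_tfbs_within_100" = genes with no site in [-no_tfbs_within, 0); plus
    "all_genes". Empty classes are omitted with a warning.
    """
    if depths.window < window:
        raise ValueError("depth window narrower than requested profile window")
    sites = _sites_by_gene(tfbs)
    classes: dict[str, list[str]] = {"all_genes": [g.gene_id for g in genes]}
    for anchor in anchors:
        classes[f"tfbs_at_{anchor}"] = [
            g.gene_id
            for g in genes
            if any(abs(off - anchor) <= tolerance_bp for off in sites.get(g.gene_id, ()))
        ]
    classes[f"no_tfbs_within_{no_tfbs_within}"] = [
        g.gene_id
        for g in genes
        if not any(-no_tfbs_within <= off < 0 for off in sites.get(g.gene_id, ()))
    ]

    off = depths.window - window
    out: dict[str, TssProfile] = {}
    for name, ids in classes.items():
        if not ids:
            logger.warning("conditional_profiles: class %s is empty, omitted", name)
            continue
        acc = np.zeros(2 * window // bin_bp)
        for g in ids:
            d = depths.depth[g]
            if off:
                d = d[off:-off]
            acc += bin_depth(d, bin_bp)
        out[name] = TssProfile(window=window, bin_bp=bin_bp, values=acc / len(ids), n_genes=len(ids))
        logger.info("conditional_profiles: class %s has %d genes", name, len(ids))
    return out


def categorize_tfbs(
    genes: Sequence[GeneAnnotation],
    tfbs: Sequence[TfbsSite],
    promoter_bp: int = 2000,
    proximal_bp: int = 150,
) -> pd.Series:
    """Exhaustive, disjoint TFBS category per gene.

    NO_TFBS_IN_PROMOTER if no site in [-promoter_bp, 0); otherwise the count
    of sites in [-promoter_bp, -proximal_bp) maps 0 / 1 / >=2 to
    NONE_BEYOND_150 / ONE_BEYOND_150 / MULTI_BEYOND_150.
    """
    sites = _sites_by_gene(tfbs)
    out = {}
    for g in genes:
        offs = [o for o in sites.get(g.gene_id, ()) if -promoter_bp <= o < 0]
        if not offs:
            out[g.gene_id] = "NO_TFBS_IN_PROMOTER"
            continue
        distal = sum(1 for o in offs if o < -proximal_bp)
        if distal == 0:
            out[g.gene_id] = "NONE_BEYOND_150"
        elif distal == 1:
            out[g.gene_id] = "ONE_BEYOND_150"
        else:
            out[g.gene_id] = "MULTI_BEYOND_150"
    return pd.Series(out, name="tfbs_category")
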