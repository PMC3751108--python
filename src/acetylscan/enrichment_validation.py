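"""Gene-set enrichment (hypergeometric + Benjamini-Hochberg) and
comparative-Cp qPCR fold-change statistics.

The enrichment test is the standard over-representation setup: for a query
of n genes drawn from a universe of N, a category of K genes overlapping the
query in k genes has upper-tail p = P(X >= k) with X ~ Hypergeom(N, K, n).
qPCR quantification is the comparative crossing-point method with an assumed
amplification efficiency of 2: fold change per sample is
2^(mean control dCp - sample dCp), so the control group mean is 1 by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "hypergeometric_enrichment",
    "QpcrMeasurement",
    "qpcr_fold_change",
    "QpcrResult",
    "read_gmt",
]


@dataclass
class EnrichmentResult:
    category_id: str
    universe_size: int
    category_size: int
    query_size: int
    overlap: int
    p_value: float
    adjusted_p: float
    fold_enrichment: float


def hypergeometric_enrichment(
    query: set[str],
    categories: Mapping[str, set[str]],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test per category with BH adjustment.

    Categories are intersected with the universe; the query must be a subset
    of the universe. Results are sorted by adjusted p (ties by raw p, then
    category id).
    """
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for cat_id, members in categories.items():
        cat = set(members) & universe
        K = len(cat)
        k = len(cat & query)
        # P(X >= k); sf(k-1) is the exact upper tail
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        fold = (k / n) / (K / N) if K else 0.0
        rows.append((cat_id, K, k, min(max(p, 0.0), 1.0), fold))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    results = [
        EnrichmentResult(
            category_id=cat_id,
            universe_size=N,
            category_size=K,
            query_size=n,
            overlap=k,
            p_value=p,
            adjusted_p=float(adj),
            fold_enrichment=fold,
        )
        for (cat_id, K, k, p, fold), adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.category_id))
    return results


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene-set files: name <TAB> description <TAB> gene1 <TAB> ..."""
    out: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {ln[:80]}")
        out[fields[0]] = {g for g in fields[2:] if g}
    return out


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR sample: crossing-point cycles for target and reference gene."""

    sample_id: str
    group: str  # "FC" or "Control"
    cp_target: float
    cp_reference: float

    @property
    def delta_cp(self) -> float:
        return self.cp_target - self.cp_reference


@dataclass
class QpcrResult:
    fold_change: dict[str, float]  # group -> mean fold change
    sem: dict[str, float]
    p_value: float
    n: dict[str, int]


def qpcr_fold_change(
    measurements: Sequence[QpcrMeasurement],
    control_group: str = "Control",
    paired: bool = False,
) -> QpcrResult:
    """Comparative-Cp fold changes relative to the control-group mean.

    Per sample: dCp = Cp_target − Cp_reference; fold = 2^(mean control dCp −
    dCp). Group summaries are mean ± SEM; the between-group test on dCp is
    Welch's two-tailed t-test by default, or a paired t-test when ``paired``
    and sample_ids match one-to-one across groups.
    """
    valid = [
        m for m in measurements
        if np.isfinite(m.cp_target) and np.isfinite(m.cp_reference)
    ]
    dropped = len(measurements) - len(valid)
    if dropped:
        logger.info("qpcr_fold_change: dropped %d samples with missing Cp", dropped)
    groups = sorted({m.group for m in valid})
    if control_group not in groups or len(groups) != 2:
        raise ValueError("need exactly two groups including the control group")
    by_group = {g: [m for m in valid if m.group == g] for g in groups}
    for g, ms in by_group.items():
        if len(ms) < 2:
            raise ValueError(f"group {g}: need >= 2 samples")
    ctrl_mean_dcp = float(np.mean([m.delta_cp for m in by_group[control_group]]))

    fold, sem, n = {}, {}, {}
    for g, ms in by_group.items():
        f = np.array([2.0 ** (ctrl_mean_dcp - m.delta_cp) for m in ms])
        # group fold change is averaged on the dCp (log2) scale, so the
        # control group is exactly 1 by construction; SEM from sample folds
        fold[g] = float(2.0 ** (ctrl_mean_dcp - np.mean([m.delta_cp for m in ms])))
        sem[g] = float(f.std(ddof=1) / np.sqrt(len(f)))
        n[g] = len(f)

    treated = next(g for g in groups if g != control_group)
    x = np.array([m.delta_cp for m in by_group[treated]])
    y = np.array([m.delta_cp for m in by_group[control_group]])
    if paired:
        tx = sorted(by_group[treated], key=lambda m: m.sample_id)
        ty = sorted(by_group[control_group], key=lambda m: m.sample_id)
        if len(tx) != len(ty) or [m.sample_id for m in tx] != [m.sample_id for m in ty]:
            raise ValueError("paired mode requires matching sample_ids across groups")
        p = float(stats.ttest_rel([m.delta_cp for m in tx], [m.delta_cp for m in ty]).pvalue)
    else:
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    return QpcrResult(fold_change=fold, sem=sem, p_value=p, n=n)


def read_qpcr_tsv(path: str | Path) -> list[QpcrMeasurement]:
    """TSV columns: sample_id, group, cp_target, cp_reference (header required)."""
    df = pd.read_csv(path, sep="\t")
    return [
        QpcrMeasurement(str(r.sample_id), str(r.group), float(r.cp_target), float(r.cp_reference))
        for r in df.itertuples(index=False)
    ]
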