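"""Criteria-based gene selection, set overlaps, and peak annotation.

The selection rules are read-count thresholds on promoter coverage:

* *above average*: promoter reads strictly greater than a threshold derived
  from the dataset mean (mean rounded up to the nearest 10 — e.g. a mean of
  45 gives 50);
* *differential* ("Diff" rule): promoter reads > ``up`` in the treated
  group and <= ``down`` in controls (defaults 50 / 40).

Peak-caller output (BED, MACS xls, SICER summary) is consumed through
adapters and annotated by summit distance to the nearest TSS.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneAnnotation, GenomicInterval, tss_relative_offset

logger = logging.getLogger(__name__)

__all__ = [
    "PeakRecord",
    "GeneSetReport",
    "derive_threshold",
    "above_average_genes",
    "differential_by_criteria",
    "overlap_report",
    "annotate_peaks",
    "PeakAnnotation",
    "read_peak_files",
]

DISTANCE_BINS = (
    ("upstream_-4000_-2000", -4000, -2000),
    ("promoter_-2000_0", -2000, 0),
    ("cds_0_2000", 0, 2000),
)


@dataclass(frozen=True)
class PeakRecord:
    """A called enrichment peak; 0-based half-open, optional summit/score."""

    interval: GenomicInterval
    score: float | None = None
    summit: int | None = None  # absolute coordinate

    @property
    def anchor(self) -> int:
        """Summit if present, else interval midpoint."""
        if self.summit is not None:
            return self.summit
        return (self.interval.start + self.interval.end) // 2


def derive_threshold(
    scores: pd.DataFrame, mode: str = "auto", manual_value: int | None = None
) -> int:
    """Above-average threshold: mean promoter reads rounded up to nearest 10."""
    if mode == "manual":
        if manual_value is None:
            raise ValueError("manual mode requires manual_value")
        return int(manual_value)
    if mode != "auto":
        raise ValueError(f"unknown mode: {mode}")
    if not len(scores):
        raise ValueError("derive_threshold requires non-empty scores")
    mean = float(scores["promoter_reads"].mean())
    return int(math.ceil(mean / 10.0)) * 10


def above_average_genes(scores: pd.DataFrame, threshold: int) -> set[str]:
    """Genes whose promoter read count strictly exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not len(scores):
        return set()
    return set(scores.index[scores["promoter_reads"] > threshold])


def differential_by_criteria(
    fc_scores: pd.DataFrame,
    ctrl_scores: pd.DataFrame,
    up: int = 50,
    down: int = 40,
) -> set[str]:
    """Diff rule: promoter reads > up in treated AND <= down in control.

    A gene missing from one condition is treated as 0 reads there.
    """
    universe = fc_scores.index.union(ctrl_scores.index)
    missing = len(universe) - min(len(fc_scores), len(ctrl_scores))
    if len(fc_scores) != len(universe) or len(ctrl_scores) != len(universe):
        logger.info("differential_by_criteria: unequal gene universes, missing counts as 0")
    fc = fc_scores["promoter_reads"].reindex(universe, fill_value=0)
    ctrl = ctrl_scores["promoter_reads"].reindex(universe, fill_value=0)
    return set(universe[(fc > up) & (ctrl <= down)])


@dataclass
class GeneSetReport:
    """Named gene sets with pairwise / full overlaps and unique counts.

    ``pct_of`` percentages are 100 * |A∩B| / |reference set|.
    ``unique_minimal`` is |A| − |A ∩ union(others)| (genes in no other set);
    ``unique_pairwise`` holds |A| − |A∩B| per pair, the other printed
    convention for two-set Venn margins.
    """

    sets: dict[str, set[str]]
    pairwise: dict[tuple[str, str], int]
    full_intersection: int
    unique_minimal: dict[str, int]

    def pct_of(self, a: str, b: str, reference: str) -> float:
        key = (a, b) if (a, b) in self.pairwise else (b, a)
        return 100.0 * self.pairwise[key] / len(self.sets[reference])

    def unique_pairwise(self, a: str, b: str) -> int:
        key = (a, b) if (a, b) in self.pairwise else (b, a)
        return len(self.sets[a]) - self.pairwise[key]

    def to_dict(self) -> dict:
        return {
            "sizes": {k: len(v) for k, v in self.sets.items()},
            "pairwise": {f"{a}&{b}": n for (a, b), n in self.pairwise.items()},
            "full_intersection": self.full_intersection,
            "unique_to_set": self.unique_minimal,
            "pct": {
                f"{a}&{b}_of_{r}": round(self.pct_of(a, b, r), 1)
                for (a, b) in self.pairwise
                for r in (a, b)
            },
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def overlap_report(sets: Mapping[str, set[str]]) -> GeneSetReport:
    """All pairwise and full intersections of >= 2 named gene sets."""
    if len(sets) < 2:
        raise ValueError("overlap_report needs at least two sets")
    names = list(sets)
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(names, 2)
    }
    full = set.intersection(*[set(sets[n]) for n in names])
    unique = {
        n: len(set(sets[n]) - set.union(*[set(sets[m]) for m in names if m != n]))
        for n in names
    }
    return GeneSetReport(
        sets={n: set(v) for n, v in sets.items()},
        pairwise=pairwise,
        full_intersection=len(full),
        unique_minimal=unique,
    )


@dataclass
class PeakAnnotation:
    """Peaks binned by TSS distance; genic peaks mapped to unique genes."""

    per_peak: pd.DataFrame  # chrom, anchor, gene_id, offset, bin
    bin_counts: dict[str, int]
    genes: list[str]  # unique genes of non-intergenic peaks, sorted


def annotate_peaks(
    peaks: Sequence[PeakRecord], genes: Sequence[GeneAnnotation]
) -> PeakAnnotation:
    """Locate each peak by its summit (or midpoint) relative to the nearest TSS.

    Nearest TSS on the same chromosome (ties broken by lexicographic
    gene_id); binned [-4000,-2000), [-2000,0), [0,+2000), else intergenic.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_arrays = {
        c: (
            np.array([g.tss for g in sorted(gs, key=lambda g: (g.tss, g.gene_id))]),
            [g for g in sorted(gs, key=lambda g: (g.tss, g.gene_id))],
        )
        for c, gs in by_chrom.items()
    }

    rows = []
    for p in peaks:
        chrom, anchor = p.interval.chrom, p.anchor
        gene_id, offset, label = None, None, "intergenic"
        if chrom in tss_arrays:
            tss, gs = tss_arrays[chrom]
            i = int(np.searchsorted(tss, anchor))
            cands = [gs[j] for j in (i - 1, i, i + 1) if 0 <= j < len(gs)]
            best = min(cands, key=lambda g: (abs(anchor - g.tss), g.gene_id))
            gene_id = best.gene_id
            offset = tss_relative_offset(best, anchor)
            for name, lo, hi in DISTANCE_BINS:
                if lo <= offset < hi:
                    label = name
                    break
        rows.append(
            {"chrom": chrom, "anchor": anchor, "gene_id": gene_id, "offset": offset, "bin": label}
        )
    per_peak = pd.DataFrame(rows, columns=["chrom", "anchor", "gene_id", "offset", "bin"])
    bin_counts = {name: 0 for name, _, _ in DISTANCE_BINS}
    bin_counts["intergenic"] = 0
    for label in per_peak["bin"]:
        bin_counts[label] += 1
    genic = per_peak.loc[per_peak["bin"] != "intergenic", "gene_id"].dropna()
    return PeakAnnotation(
        per_peak=per_peak, bin_counts=bin_counts, genes=sorted(set(genic))
    )


def read_peak_files(path: str | Path, dialect: str = "BED") -> list[PeakRecord]:
    """Read external peak-caller output into normalized PeakRecords.

    Dialects: ``BED`` (0-based; optional score in column 5), ``MACS-xls``
    (1-based inclusive, tab-separated with header; summit column stored as
    an absolute coordinate), ``SICER`` (0-based summary table).
    """
    path = Path(path)
    dialect = dialect.upper()
    peaks: list[PeakRecord] = []
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith(("#", "track"))
    ]
    if not lines:
        logger.warning("empty peak file %s", path)
        return []
    if dialect == "BED":
        for ln in lines:
            f = ln.split("\t") if "\t" in ln else ln.split()
            score = float(f[4]) if len(f) >= 5 else None
            peaks.append(
                PeakRecord(GenomicInterval(f[0], int(f[1]), int(f[2])), score=score)
            )
    elif dialect in ("MACS", "MACS-XLS"):
        header = None
        for ln in lines:
            f = ln.split("\t")
            if header is None and f[0].lower() in ("chr", "chrom", "chromosome"):
                header = [h.lower() for h in f]
                continue
            if header is None:
                header = ["chr", "start", "end", "length", "summit", "tags",
                          "-10*log10(pvalue)", "fold_enrichment"][: len(f)]
            rec = dict(zip(header, f))
            start = int(rec["start"]) - 1  # MACS xls is 1-based inclusive
            end = int(rec["end"])
            summit = int(rec["summit"]) if "summit" in rec else None
            score = float(rec.get("-10*log10(pvalue)", "nan"))
            peaks.append(
                PeakRecord(
                    GenomicInterval(rec["chr"], start, end),
                    score=None if math.isnan(score) else score,
                    summit=summit,
                )
            )
    elif dialect == "SICER":
        for ln in lines:
            f = ln.split("\t")
            score = float(f[5]) if len(f) > 5 else None
            peaks.append(
                PeakRecord(GenomicInterval(f[0], int(f[1]), int(f[2])), score=score)
            )
    else:
        raise ValueError(f"unknown peak dialect: {dialect}")
    return peaks


def write_gene_set(genes: set[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_set(path: str | Path) -> set[str]:
    return {ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()}
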