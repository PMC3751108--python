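"""Read classification over genomic features and TSS-anchored coverage.

A read belongs to a feature if it overlaps it by at least one base. A read
spanning the TSS therefore counts toward both the promoter and the gene
body, so feature percentages may sum to more than 100 — this double-count
rule is deliberate and mirrors how promoter/CDS shares are reported for
acetylation ChIP-seq.

Metagene ("TSS profile") values are base-level read depth, binned and
averaged over genes, with minus-strand genes mirrored so that negative
offsets are always upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import GeneAnnotation, GenomicInterval, promoter_interval

logger = logging.getLogger(__name__)

__all__ = [
    "ReadSet",
    "FeatureDistribution",
    "TssProfile",
    "GeneDepths",
    "read_bed",
    "read_sam",
    "classify_reads",
    "tss_profile",
    "per_gene_depth",
    "gene_scores",
    "enrichment_delta",
    "EnrichmentDelta",
    "depth_intervals",
    "write_track",
    "read_bedgraph",
]


class ReadSet:
    """Aligned read intervals for one sample, held as per-chromosome arrays.

    ``group`` is the experimental condition (e.g. "FC" for fear-conditioned,
    "Control"); ``antibody`` names the immunoprecipitation (e.g. "H4K5ac",
    "H4K12ac", "IgG").
    """

    def __init__(
        self,
        chroms: Sequence[str],
        starts: Sequence[int],
        ends: Sequence[int],
        sample_label: str = "",
        group: str = "",
        antibody: str = "",
    ) -> None:
        self.df = pd.DataFrame(
            {
                "chrom": pd.Series(chroms, dtype=str),
                "start": np.asarray(starts, dtype=np.int64),
                "end": np.asarray(ends, dtype=np.int64),
            }
        )
        if len(self.df) and (self.df["end"] <= self.df["start"]).any():
            raise ValueError("all reads must have positive length")
        self.sample_label = sample_label
        self.group = group
        self.antibody = antibody
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval], **meta) -> "ReadSet":
        ivs = list(intervals)
        return cls(
            [iv.chrom for iv in ivs],
            [iv.start for iv in ivs],
            [iv.end for iv in ivs],
            **meta,
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_reads(self) -> int:
        return len(self.df)

    def chrom_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts sorted ascending, ends sorted ascending).

        The two arrays are sorted independently: counting reads overlapping
        [s, e) needs only |{start < e}| - |{end <= s}|, which is pairing-free.
        """
        if self._index is None:
            idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, sub in self.df.groupby("chrom", sort=False):
                idx[str(chrom)] = (
                    np.sort(sub["start"].to_numpy()),
                    np.sort(sub["end"].to_numpy()),
                )
            self._index = idx
        return self._index

    def reads_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """(start, end) pairs of reads overlapping [start, end)."""
        sub = self.df[self.df["chrom"] == chrom]
        mask = (sub["start"] < end) & (sub["end"] > start)
        return sub.loc[mask, ["start", "end"]].to_numpy()

    def write_bed(self, path: str | Path) -> None:
        df = self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
        with open(path, "w") as fh:
            for chrom, start, end in df.itertuples(index=False):
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str | Path, sample_label: str = "", group: str = "", antibody: str = "") -> ReadSet:
    """Load reads from a BED3+ file."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            comment="#",
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
    except pd.errors.EmptyDataError:
        logger.warning("empty read file %s", path)
        df = pd.DataFrame({"chrom": [], "start": [], "end": []})
    return ReadSet(
        df["chrom"].tolist(),
        df["start"].to_numpy(dtype=np.int64, copy=False) if len(df) else [],
        df["end"].to_numpy(dtype=np.int64, copy=False) if len(df) else [],
        sample_label=sample_label or path.stem,
        group=group,
        antibody=antibody,
    )


def read_sam(
    path: str | Path,
    sample_label: str = "",
    group: str = "",
    antibody: str = "",
    min_mapq: int = 0,
) -> ReadSet:
    """Load mapped reads from a SAM file via pysam, with a MAPQ filter."""
    import pysam

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for aln in fh:
            if aln.is_unmapped or aln.mapping_quality < min_mapq:
                continue
            chroms.append(aln.reference_name)
            starts.append(aln.reference_start)
            ends.append(aln.reference_end or aln.reference_start + 1)
    return ReadSet(
        chroms, starts, ends,
        sample_label=sample_label or Path(path).stem,
        group=group, antibody=antibody,
    )


# ---------------------------------------------------------------------------
# feature classification


@dataclass
class FeatureDistribution:
    """Counts of reads overlapping promoter / CDS / intergenic space.

    A TSS-spanning read increments both promoter and CDS, so percentages can
    sum above 100. ``genic`` counts reads overlapping promoter or gene body
    at least once (each read counted once).
    """

    counts: dict[str, int]
    n_reads: int
    genic: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.n_reads == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.n_reads for k, v in self.counts.items()}

    @property
    def genic_pct(self) -> float:
        return 100.0 * self.genic / self.n_reads if self.n_reads else 0.0


def _merged_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Merge to disjoint sorted intervals; returns (starts, ends)."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    if not ivs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    out_s, out_e = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def _overlaps_any(
    starts: np.ndarray, ends: np.ndarray, merged: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Vectorized: does each [start, end) hit any merged interval?"""
    ms, me = merged
    if len(ms) == 0 or len(starts) == 0:
        return np.zeros(len(starts), dtype=bool)
    idx = np.searchsorted(ms, ends, side="left")  # first interval starting >= end
    hit = idx > 0
    prev = np.clip(idx - 1, 0, len(ms) - 1)
    return hit & (me[prev] > starts)


def classify_reads(
    reads: ReadSet,
    genes: Sequence[GeneAnnotation],
    promoter_bp: int = 5000,
) -> FeatureDistribution:
    """Assign every read to promoter / CDS / intergenic by >=1 bp overlap."""
    if not genes:
        raise ValueError("classify_reads requires a non-empty annotation set")
    prom_by_chrom: dict[str, list[tuple[int, int]]] = {}
    body_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        prom = promoter_interval(g, promoter_bp)
        if len(prom):
            prom_by_chrom.setdefault(g.chrom, []).append((prom.start, prom.end))
        body_by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    prom_merged = {c: _merged_intervals(v) for c, v in prom_by_chrom.items()}
    body_merged = {c: _merged_intervals(v) for c, v in body_by_chrom.items()}

    n_prom = n_body = n_inter = 0
    known_chroms = set(body_merged)
    for chrom, sub in reads.df.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if chrom not in known_chroms:
            logger.info(
                "%d reads on %s absent from annotation -> intergenic", len(sub), chrom
            )
            n_inter += len(sub)
            continue
        empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
        in_prom = _overlaps_any(starts, ends, prom_merged.get(str(chrom), empty))
        in_body = _overlaps_any(starts, ends, body_merged[str(chrom)])
        n_prom += int(in_prom.sum())
        n_body += int(in_body.sum())
        n_inter += int((~in_prom & ~in_body).sum())
    genic = reads.n_reads - n_inter
    return FeatureDistribution(
        counts={"promoter": n_prom, "CDS": n_body, "intergenic": n_inter},
        n_reads=reads.n_reads,
        genic=genic,
    )


# ---------------------------------------------------------------------------
# TSS-anchored depth


@dataclass
class TssProfile:
    """Mean base-level depth per bin over a window centered on the TSS.

    ``values[j]`` is the depth (reads-per-base) averaged within bin j and
    over genes; bin j covers offsets [-window + j*bin_bp, -window + (j+1)*bin_bp).
    ``normalized`` rescales to percent of total profile mass (the display
    convention of "percentage of reads" metagene plots).
    """

    window: int
    bin_bp: int
    values: np.ndarray
    n_genes: int

    @property
    def offsets(self) -> np.ndarray:
        """Left edge of each bin, TSS-relative."""
        return np.arange(-self.window, self.window, self.bin_bp)

    @property
    def normalized(self) -> np.ndarray:
        total = self.values.sum()
        return 100.0 * self.values / total if total > 0 else np.zeros_like(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean_depth": self.values, "pct_of_mass": self.normalized}
        )

    def peak_offset(self, lo: int, hi: int, halfwin_bins: int = 15) -> float:
        """Locate the profile peak within offsets [lo, hi) by parabolic fit.

        Fits a quadratic to the bins around the zone maximum (standard
        sub-bin peak interpolation) and returns the vertex offset in bp;
        falls back to the maximum bin center if the fit is not concave.
        """
        zone = (self.offsets >= lo) & (self.offsets < hi)
        if not zone.any():
            raise ValueError(f"no bins in [{lo}, {hi})")
        centers = self.offsets[zone] + self.bin_bp / 2.0
        v = self.values[zone]
        i = int(np.argmax(v))
        a, b = max(0, i - halfwin_bins), min(len(v), i + halfwin_bins + 1)
        coef = np.polyfit(centers[a:b], v[a:b], 2)
        if coef[0] < 0:
            vertex = -coef[1] / (2.0 * coef[0])
            return float(np.clip(vertex, centers[a], centers[b - 1]))
        return float(centers[i])


@dataclass
class GeneDepths:
    """Per-gene base-level depth over a TSS-centered, strand-oriented window.

    ``depth[gene_id][i]`` is the read depth at TSS-relative offset
    ``i - window``.
    """

    window: int
    depth: dict[str, np.ndarray]

    def at(self, gene_id: str, offset: int) -> float:
        if not (-self.window <= offset < self.window):
            raise ValueError(f"offset {offset} outside +/-{self.window} window")
        return float(self.depth[gene_id][offset + self.window])


def per_gene_depth(
    reads: ReadSet, genes: Sequence[GeneAnnotation], window: int
) -> GeneDepths:
    """Base-level depth per gene over [-window, +window) around the TSS.

    Minus-strand genes are mirrored so the array is always oriented
    upstream -> downstream.
    """
    index = reads.chrom_index()
    # max read length per chromosome bounds the candidate search window
    max_len: dict[str, int] = {}
    for chrom, sub in reads.df.groupby("chrom", sort=False):
        max_len[str(chrom)] = int((sub["end"] - sub["start"]).max()) if len(sub) else 0
    # need paired (start, end); sort once by start, keep paired ends
    paired: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in reads.df.groupby("chrom", sort=False):
        order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
        paired[str(chrom)] = (
            sub["start"].to_numpy()[order],
            sub["end"].to_numpy()[order],
        )

    out: dict[str, np.ndarray] = {}
    for g in genes:
        d = np.zeros(2 * window, dtype=np.float64)
        if g.strand == "+":
            lo, hi = g.tss - window, g.tss + window  # genomic [lo, hi)
        else:
            lo, hi = g.tss - window + 1, g.tss + window + 1
        if g.chrom in paired:
            starts, ends = paired[g.chrom]
            ml = max_len[g.chrom]
            i0 = np.searchsorted(starts, lo - ml, side="left")
            i1 = np.searchsorted(starts, hi, side="left")
            for s, e in zip(starts[i0:i1], ends[i0:i1]):
                a, b = max(s, lo), min(e, hi)
                if a >= b:
                    continue
                d[a - lo : b - lo] += 1.0
        if g.strand == "-":
            d = d[::-1]
        out[g.gene_id] = d
    return GeneDepths(window=window, depth=out)


def bin_depth(depth: np.ndarray, bin_bp: int) -> np.ndarray:
    """Mean depth per bin of width bin_bp."""
    n = len(depth) // bin_bp
    return depth[: n * bin_bp].reshape(n, bin_bp).mean(axis=1)


def tss_profile(
    reads: ReadSet,
    genes: Sequence[GeneAnnotation],
    window: int,
    bin_bp: int = 10,
    depths: GeneDepths | None = None,
) -> TssProfile:
    """Metagene profile: per-bin mean depth averaged over all genes."""
    if not genes:
        raise ValueError("tss_profile requires at least one gene")
    if window % bin_bp != 0:
        raise ValueError("window must be a multiple of bin_bp")
    if depths is None:
        depths = per_gene_depth(reads, genes, window)
    acc = np.zeros(2 * window // bin_bp, dtype=np.float64)
    for g in genes:
        acc += bin_depth(depths.depth[g.gene_id], bin_bp)
    return TssProfile(window=window, bin_bp=bin_bp, values=acc / len(genes), n_genes=len(genes))


# ---------------------------------------------------------------------------
# per-gene scores


def gene_scores(
    reads: ReadSet,
    genes: Sequence[GeneAnnotation],
    promoter_bp: int = 5000,
    window: int = 5000,
) -> pd.DataFrame:
    """Per-gene read counts: promoter, gene body (CDS), and +/-window of TSS.

    A read overlapping features of two genes increments both genes. Returns
    a DataFrame indexed by gene_id with integer columns ``promoter_reads``,
    ``cds_reads``, ``window_score``.
    """
    index = reads.chrom_index()

    def count(chrom: str, start: int, end: int) -> int:
        if chrom not in index or end <= start:
            return 0
        starts, ends = index[chrom]
        return int(
            np.searchsorted(starts, end, side="left")
            - np.searchsorted(ends, start, side="right")
        )

    rows = []
    for g in genes:
        prom = promoter_interval(g, promoter_bp)
        if g.strand == "+":
            wlo, whi = g.tss - window, g.tss + window
        else:
            wlo, whi = g.tss - window + 1, g.tss + window + 1
        rows.append(
            {
                "gene_id": g.gene_id,
                "promoter_reads": count(g.chrom, prom.start, prom.end),
                "cds_reads": count(g.chrom, g.start, g.end),
                "window_score": count(g.chrom, max(0, wlo), whi),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class EnrichmentDelta:
    """Percentage-point differences between two feature distributions."""

    delta_pct: dict[str, float]
    delta_genic_pct: float
    delta_genic_reads: int


def enrichment_delta(chip: FeatureDistribution, control: FeatureDistribution) -> EnrichmentDelta:
    """ChIP minus control share per category, in percentage points."""
    if chip.n_reads == 0 or control.n_reads == 0:
        raise ValueError("enrichment_delta undefined for zero-read distributions")
    cp, kp = chip.percentages, control.percentages
    return EnrichmentDelta(
        delta_pct={k: cp[k] - kp.get(k, 0.0) for k in cp},
        delta_genic_pct=chip.genic_pct - control.genic_pct,
        delta_genic_reads=chip.genic - control.genic,
    )


# ---------------------------------------------------------------------------
# track output


def depth_intervals(reads: ReadSet, chrom: str) -> list[tuple[int, int, float]]:
    """Run-length depth over one chromosome as (start, end, depth) runs, depth > 0."""
    sub = reads.df[reads.df["chrom"] == chrom]
    if not len(sub):
        return []
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    events = np.concatenate([starts, ends])
    deltas = np.concatenate([np.ones(len(starts)), -np.ones(len(ends))])
    order = np.argsort(events, kind="mergesort")
    events, deltas = events[order], deltas[order]
    runs: list[tuple[int, int, float]] = []
    depth = 0.0
    pos = int(events[0])
    for ev, dl in zip(events, deltas):
        ev = int(ev)
        if ev != pos:
            if depth > 0:
                runs.append((pos, ev, depth))
            pos = ev
        depth += dl
    return runs


def write_track(
    source: ReadSet | Mapping[str, Sequence[tuple[int, int, float]]],
    path: str | Path,
    format: str = "bedGraph",
    track_name: str | None = None,
) -> None:
    """Write a coverage track as bedGraph (0-based) or fixedStep wig (1-based).

    ``source`` is either a ReadSet (depth computed here) or a mapping
    chrom -> iterable of (start, end, value) runs in 0-based half-open
    coordinates. Output is sorted by chromosome and start; zero-depth runs
    are omitted, so an all-zero input yields an empty track body.
    """
    if isinstance(source, ReadSet):
        chroms = sorted(source.df["chrom"].unique())
        runs = {c: depth_intervals(source, c) for c in chroms}
    else:
        runs = {c: sorted(source[c]) for c in sorted(source)}
    fmt = format.lower()
    with open(path, "w") as fh:
        if track_name:
            ttype = "bedGraph" if fmt == "bedgraph" else "wiggle_0"
            fh.write(f'track type={ttype} name="{track_name}"\n')
        for chrom in sorted(runs):
            for start, end, value in runs[chrom]:
                if value == 0:
                    continue
                if fmt == "bedgraph":
                    fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
                elif fmt == "wig":
                    # wiggle is 1-based; one fixedStep block per run
                    fh.write(f"fixedStep chrom={chrom} start={start + 1} step=1 span=1\n")
                    for _ in range(start, end):
                        fh.write(f"{value:g}\n")
                else:
                    raise ValueError(f"unknown track format: {format}")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            c, s, e, v = line.split("\t")
            out.append((c, int(s), int(e), float(v)))
    return out
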