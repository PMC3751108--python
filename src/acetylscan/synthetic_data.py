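"""Seeded generator of synthetic annotations, expression, TFBS and ChIP reads.

The generator emulates the statistical structure the downstream analysis
assumes for an acetylation mark of active chromatin:

* a bimodal TSS-anchored signal with a promoter mode (default −800 bp) and
  a gene-body mode (default +1000 bp), plus a uniform gene-body component
  that extends coverage toward the TTS (``cds_extension="to_TTS"``, the
  H4K5ac-like shape) or stays proximal (``"proximal_only"``, H4K12ac-like);
* per-gene signal read counts Poisson-distributed with mean coupled to the
  gene's expression rank, so acetylation correlates with expression;
* a near-uniform genome-wide background; an IgG ("mock IP") sample is
  background only, at its own (higher) rate because a mock library is
  sequenced to comparable depth without enrichment;
* optional TFBS-dependent modulation: genes lacking a TFBS proximal to the
  TSS get a configurable amplitude boost;
* planted group-specific differential genes (amplitude multiplier in the
  affected group only) for testing differential selection.

Everything is driven by a single integer seed; outputs are byte-identical
across runs with the same config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import ReadSet
from .genome_model import GeneAnnotation, TfbsSite, write_annotations, write_tfbs

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_genome",
    "simulate_expression",
    "simulate_reads",
    "simulate_study",
]

GROUPS = ("FC", "Control")


@dataclass
class SimulationConfig:
    """All knobs of the generator. Defaults define the reference study
    conditions used throughout the test-suite; see docs/methods.md for the
    rationale behind each value."""

    seed: int = 0
    n_genes: int = 2000
    n_chroms: int = 2
    gene_length: tuple[int, int] = (2000, 8000)
    intergenic_gap: tuple[int, int] = (6000, 20000)
    chrom_margin: int = 20000  # bare sequence before first / after last gene

    # expression (log2 intensity scale)
    expression_mean: float = 8.0
    expression_sd: float = 2.0
    n_samples_per_group: int = 3
    sample_noise_sd: float = 0.25

    # signal shape (TSS-relative bp)
    promoter_mode_bp: int = -800
    cds_mode_bp: int = 1000
    mode_sd_bp: int = 250
    promoter_weight: float = 0.45
    cds_weight: float = 0.35
    body_weight: float = 0.20
    cds_extension: str = "to_TTS"  # or "proximal_only"

    # read counts
    base_reads: float = 40.0
    coupling_slope: float = 0.02  # signal reads per expression-rank unit
    background_rate: float = 0.5  # ChIP background, reads per kb
    igg_rate: float = 2.0  # mock-IP rate, reads per kb
    read_length: int = 50

    # TFBS
    tfbs_sites_mean: float = 2.0  # Poisson mean sites per promoter
    tfbs_promoter_bp: int = 2000
    tfbs_proximal_prob: float = 0.6  # per-site probability of landing proximal
    tfbs_proximal_window: int = 150
    tfbs_boost_factor: float = 1.0  # amplitude x for genes with no site near TSS
    tfbs_boost_window: int = 100

    # planted differential genes
    n_planted: int = 100
    amplitude_multiplier: float = 3.0
    affected_group: str = "FC"

    def validate(self) -> None:
        if self.n_genes < 0 or self.read_length <= 0:
            raise ValueError("n_genes must be >= 0 and read_length positive")
        for rate in (self.background_rate, self.igg_rate, self.base_reads,
                     self.coupling_slope, self.tfbs_sites_mean):
            if rate < 0:
                raise ValueError("rates must be non-negative")
        if self.n_planted > self.n_genes:
            raise ValueError("cannot plant more differential genes than genes")
        if self.cds_extension not in ("to_TTS", "proximal_only"):
            raise ValueError(f"unknown cds_extension: {self.cds_extension}")
        w = self.promoter_weight + self.cds_weight + self.body_weight
        if w <= 0:
            raise ValueError("mixture weights must sum to a positive value")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    amplitude: dict[str, dict[str, float]]  # group -> gene_id -> multiplier
    planted: list[str]
    boosted: list[str]  # genes with no proximal TFBS (boost applies if factor != 1)
    expression_rank: dict[str, int]
    signal_mean: dict[str, float]  # per-gene base Poisson mean (unmodulated)

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": self.planted,
                "boosted": self.boosted,
                "expression_rank": self.expression_rank,
                "signal_mean": self.signal_mean,
                "amplitude": self.amplitude,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SimulatedStudy:
    """Bundle of one complete synthetic experiment."""

    config: SimulationConfig
    genes: list[GeneAnnotation]
    chrom_sizes: dict[str, int]
    tfbs: list[TfbsSite]
    expression: pd.DataFrame  # genes x samples, log2 intensities
    readsets: dict[tuple[str, str], ReadSet]  # (group, antibody) -> reads
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Emit genes.bed, tfbs.tsv, expression.tsv, reads_*.bed, truth.json
        and a manifest recording the seed and all paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"genes": "genes.bed", "tfbs": "tfbs.tsv", "expression": "expression.tsv",
                 "truth": "truth.json"}
        write_annotations(self.genes, outdir / paths["genes"])
        write_tfbs(self.tfbs, outdir / paths["tfbs"])
        self.expression.to_csv(outdir / paths["expression"], sep="\t")
        (outdir / paths["truth"]).write_text(self.truth.to_json() + "\n")
        for (group, antibody), rs in sorted(self.readsets.items()):
            name = f"reads_{group}_{antibody}.bed"
            rs.write_bed(outdir / name)
            paths[f"reads_{group}_{antibody}"] = name
        manifest = {
            "seed": self.config.seed,
            "config": dataclasses.asdict(self.config),
            "files": paths,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return paths


def _rng_for(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_genome(
    config: SimulationConfig,
) -> tuple[list[GeneAnnotation], dict[str, int], list[TfbsSite]]:
    """Non-overlapping gene bodies on ``n_chroms`` chromosomes plus TFBS.

    Genes are laid out left to right with random lengths and intergenic
    gaps; strands are random. TFBS offsets are drawn over the promoter
    window with a configurable proximal bias (transcription-factor sites
    cluster within ~150 bp of the TSS in real promoters).
    """
    config.validate()
    rng = _rng_for(config, 1)
    genes: list[GeneAnnotation] = []
    chrom_sizes: dict[str, int] = {}
    if config.n_genes:
        per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
        per_chrom[: config.n_genes % config.n_chroms] += 1
        gid = 0
        for c in range(config.n_chroms):
            chrom = f"chr{c + 1}"
            pos = config.chrom_margin
            for _ in range(int(per_chrom[c])):
                pos += int(rng.integers(*config.intergenic_gap))
                length = int(rng.integers(*config.gene_length))
                strand = "+" if rng.random() < 0.5 else "-"
                gid += 1
                genes.append(
                    GeneAnnotation(f"gene{gid:05d}", chrom, strand, pos, pos + length)
                )
                pos += length
            chrom_sizes[chrom] = pos + config.chrom_margin
    else:
        chrom_sizes = {"chr1": 2 * config.chrom_margin}

    min_gap = config.intergenic_gap[0]
    for a, b in zip(genes, genes[1:]):
        if a.chrom == b.chrom and b.start - a.end < min_gap:
            raise RuntimeError("gene packing violated minimum spacing")

    tfbs: list[TfbsSite] = []
    prox = config.tfbs_proximal_window
    for g in genes:
        n_sites = int(rng.poisson(config.tfbs_sites_mean))
        for _ in range(n_sites):
            if rng.random() < config.tfbs_proximal_prob:
                offset = -int(rng.integers(1, prox + 1))
            else:
                offset = -int(rng.integers(prox + 1, config.tfbs_promoter_bp + 1))
            tfbs.append(TfbsSite(g.gene_id, offset))
    return genes, chrom_sizes, tfbs


def simulate_expression(
    config: SimulationConfig, genes: list[GeneAnnotation]
) -> pd.DataFrame:
    """Per-gene log2 intensities for both groups' samples.

    Gene means are N(expression_mean, expression_sd); samples add
    independent N(0, sample_noise_sd) noise. Columns are FC_1..k then
    Control_1..k.
    """
    rng = _rng_for(config, 2)
    ids = [g.gene_id for g in genes]
    mean = rng.normal(config.expression_mean, config.expression_sd, size=len(ids))
    cols = {}
    for group in GROUPS:
        for i in range(config.n_samples_per_group):
            cols[f"{group}_{i + 1}"] = mean + rng.normal(
                0.0, config.sample_noise_sd, size=len(ids)
            )
    return pd.DataFrame(cols, index=pd.Index(ids, name="gene_id"))


def _expression_ranks(expression: pd.DataFrame) -> pd.Series:
    mean = expression.mean(axis=1)
    order = sorted(mean.index, key=lambda g: (mean[g], g))
    return pd.Series(np.arange(1, len(order) + 1), index=pd.Index(order)).reindex(mean.index)


def _gene_amplitudes(
    config: SimulationConfig,
    genes: list[GeneAnnotation],
    tfbs: list[TfbsSite],
) -> tuple[dict[str, dict[str, float]], list[str], list[str]]:
    """Per-group amplitude multipliers: TFBS boost and planted differentials."""
    rng = _rng_for(config, 3)
    proximal: set[str] = {
        s.gene_id for s in tfbs if -config.tfbs_boost_window <= s.offset < 0
    }
    boosted = [g.gene_id for g in genes if g.gene_id not in proximal]
    planted = sorted(
        rng.choice([g.gene_id for g in genes], size=config.n_planted, replace=False)
    ) if config.n_planted and genes else []
    amp: dict[str, dict[str, float]] = {grp: {} for grp in GROUPS}
    planted_set = set(planted)
    for g in genes:
        base = config.tfbs_boost_factor if g.gene_id in boosted else 1.0
        for grp in GROUPS:
            a = base
            if g.gene_id in planted_set and grp == config.affected_group:
                a *= config.amplitude_multiplier
            amp[grp][g.gene_id] = a
    return amp, planted, boosted


def simulate_reads(
    config: SimulationConfig,
    genes: list[GeneAnnotation],
    chrom_sizes: dict[str, int],
    expression: pd.DataFrame,
    group: str,
    antibody: str,
    amplitude: dict[str, float] | None = None,
    stream: int = 10,
) -> ReadSet:
    """One sample's reads: signal (unless IgG) plus uniform background.

    Per-gene signal reads ~ Poisson(amplitude * (base_reads +
    coupling_slope * expression_rank)); read centers are drawn from the
    promoter/body mixture in TSS orientation. Background reads are uniform
    over each chromosome at ``background_rate`` (ChIP) or ``igg_rate``
    (IgG) reads per kb.
    """
    config.validate()
    rng = _rng_for(config, stream)
    half = config.read_length // 2
    chroms: list[str] = []
    starts: list[np.ndarray] = []

    is_igg = antibody.upper() == "IGG"
    if not is_igg and genes:
        ranks = _expression_ranks(expression)
        for g in genes:
            amp = 1.0 if amplitude is None else amplitude.get(g.gene_id, 1.0)
            lam = amp * (config.base_reads + config.coupling_slope * float(ranks[g.gene_id]))
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            w = np.array([config.promoter_weight, config.cds_weight, config.body_weight])
            w = w / w.sum()
            comp = rng.choice(3, size=n, p=w)
            offsets = np.empty(n)
            m = comp == 0
            offsets[m] = rng.normal(config.promoter_mode_bp, config.mode_sd_bp, m.sum())
            m = comp == 1
            offsets[m] = rng.normal(config.cds_mode_bp, config.mode_sd_bp, m.sum())
            m = comp == 2
            body_end = g.length if config.cds_extension == "to_TTS" else min(g.length, 1000)
            offsets[m] = rng.uniform(0, body_end, m.sum())
            if g.strand == "+":
                centers = g.tss + offsets
            else:
                centers = g.tss - offsets
            s = np.round(centers).astype(np.int64) - half
            s = np.clip(s, 0, chrom_sizes[g.chrom] - config.read_length)
            chroms.extend([g.chrom] * n)
            starts.append(s)

    rate = config.igg_rate if is_igg else config.background_rate
    for chrom, size in sorted(chrom_sizes.items()):
        lam = rate * size / 1000.0
        n = int(rng.poisson(lam)) if lam > 0 else 0
        if n == 0:
            continue
        s = rng.integers(0, max(1, size - config.read_length), size=n)
        chroms.extend([chrom] * n)
        starts.append(s.astype(np.int64))

    all_starts = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    return ReadSet(
        chroms,
        all_starts,
        all_starts + config.read_length,
        sample_label=f"{group}_{antibody}",
        group=group,
        antibody=antibody,
    )


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run the full generator: genome, TFBS, expression, and four read sets
    (FC / Control x signal antibody / IgG) with consistent ground truth."""
    genes, chrom_sizes, tfbs = simulate_genome(config)
    expression = simulate_expression(config, genes)
    amp, planted, boosted = _gene_amplitudes(config, genes, tfbs)
    ranks = _expression_ranks(expression) if genes else pd.Series(dtype=int)
    readsets = {}
    for i, group in enumerate(GROUPS):
        readsets[(group, "H4K5ac")] = simulate_reads(
            config, genes, chrom_sizes, expression, group, "H4K5ac",
            amplitude=amp[group], stream=10 + i,
        )
        readsets[(group, "IgG")] = simulate_reads(
            config, genes, chrom_sizes, expression, group, "IgG", stream=20 + i,
        )
    truth = GroundTruth(
        amplitude=amp,
        planted=list(planted),
        boosted=boosted,
        expression_rank={g: int(r) for g, r in ranks.items()},
        signal_mean={
            g.gene_id: config.base_reads + config.coupling_slope * float(ranks[g.gene_id])
            for g in genes
        },
    )
    return SimulatedStudy(
        config=config,
        genes=genes,
        chrom_sizes=chrom_sizes,
        tfbs=tfbs,
        expression=expression,
        readsets=readsets,
        truth=truth,
    )
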