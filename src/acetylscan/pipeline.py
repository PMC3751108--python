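"""Pipeline orchestration, configuration validation, and summary arithmetic.

``run_pipeline`` drives the whole analysis from a single YAML/dict config:
simulate -> classify -> profile -> associate -> cluster -> tfbs -> select,
writing each stage's tables (TSV/JSON) into an output directory together
with a manifest recording the seed and configuration. Reruns with the same
config and seed are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import coverage, expression, gene_selection, profile_clustering, synthetic_data, tfbs_position
from .synthetic_data import SimulationConfig

logger = logging.getLogger(__name__)

__all__ = ["MappingSummary", "mapping_summary", "run_pipeline", "load_config", "DEFAULT_CONFIG"]


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero (report convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MappingSummary:
    """Sequencing/mapping arithmetic for a report header."""

    total_reads: int
    unique_reads: int
    read_length: int

    @property
    def unique_rate_pct(self) -> float:
        return _round1(100.0 * self.unique_reads / self.total_reads)

    @property
    def total_gigabases(self) -> float:
        return _round1(self.total_reads * self.read_length / 1e9)

    @property
    def mapped_gigabases(self) -> float:
        return _round1(self.unique_reads * self.read_length / 1e9)

    def to_dict(self) -> dict[str, float | int]:
        return {
            "total_reads": self.total_reads,
            "unique_reads": self.unique_reads,
            "read_length": self.read_length,
            "unique_rate_pct": self.unique_rate_pct,
            "total_gigabases": self.total_gigabases,
            "mapped_gigabases": self.mapped_gigabases,
        }


def mapping_summary(total_reads: int, unique_reads: int, read_length: int) -> MappingSummary:
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not 0 <= unique_reads <= total_reads:
        raise ValueError("unique_reads must be within [0, total_reads]")
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    return MappingSummary(total_reads, unique_reads, read_length)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {f.name: f.default for f in dataclasses.fields(SimulationConfig)
                 if f.name != "seed" and not isinstance(f.default, dataclasses._MISSING_TYPE)},
    "classify": {"promoter_bp": 5000},
    "profile": {"window": 5000, "bin_bp": 10},
    "cluster": {"window": 2000, "bin_bp": 10, "k": 5, "restarts": 10, "scaling": "unit_sum"},
    "tfbs": {"promoter_bp": 2000, "step_bp": 10, "min_depth": 1, "smooth_width": 10,
             "anchors": [-500, -800, -1100], "tolerance_bp": 25, "no_tfbs_within": 100,
             "proximal_bp": 150},
    "select": {"mode": "auto", "up": 50, "down": 40},
    "expression": {"n_bins": 10, "expressed_quantile": 0.2, "log2_transformed": True},
}
# tuple defaults are not YAML-friendly
DEFAULT_CONFIG["simulate"]["gene_length"] = list(SimulationConfig().gene_length)
DEFAULT_CONFIG["simulate"]["intergenic_gap"] = list(SimulationConfig().intergenic_gap)


def _validate_keys(cfg: Mapping[str, Any], defaults: Mapping[str, Any], path: str = "") -> None:
    for key, value in cfg.items():
        if key not in defaults:
            raise ValueError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], Mapping) and isinstance(value, Mapping):
            _validate_keys(value, defaults[key], f"{path}{key}.")


def load_config(source: str | Path | Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Merge a user config (YAML path or dict) over the defaults, validating keys."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if source is None:
        return merged
    if isinstance(source, (str, Path)):
        user = yaml.safe_load(Path(source).read_text()) or {}
    else:
        user = dict(source)
    _validate_keys(user, DEFAULT_CONFIG)
    for key, value in user.items():
        if isinstance(value, Mapping):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


# ---------------------------------------------------------------------------
# pipeline


def _sim_config(cfg: Mapping[str, Any]) -> SimulationConfig:
    kwargs = dict(cfg["simulate"])
    kwargs["gene_length"] = tuple(kwargs["gene_length"])
    kwargs["intergenic_gap"] = tuple(kwargs["intergenic_gap"])
    return SimulationConfig(seed=cfg["seed"], **kwargs)


def run_pipeline(
    config: str | Path | Mapping[str, Any] | None,
    outdir: str | Path,
    seed: int | None = None,
) -> dict[str, Any]:
    """Execute the full synthetic-study pipeline and write a report directory.

    Returns the report summary (also written as report.json). Every stage's
    outputs are TSVs named after the stage; the manifest records config and
    seed so a rerun is bit-reproducible.
    """
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": cfg["seed"]}

    # --- simulate -----------------------------------------------------
    logger.info("stage simulate: n_genes=%d", cfg["simulate"]["n_genes"])
    study = synthetic_data.simulate_study(_sim_config(cfg))
    study.write(outdir / "simulated")
    genes = study.genes
    if not genes:
        raise RuntimeError("stage simulate produced no genes; nothing to analyze")

    # --- classify -----------------------------------------------------
    promoter_bp = cfg["classify"]["promoter_bp"]
    dists = {}
    for (group, antibody), rs in sorted(study.readsets.items()):
        dists[(group, antibody)] = coverage.classify_reads(rs, genes, promoter_bp)
    rows = []
    for (group, antibody), d in sorted(dists.items()):
        row = {"group": group, "antibody": antibody, "n_reads": d.n_reads, **{
            f"{k}_pct": round(v, 1) for k, v in d.percentages.items()}}
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "classification.tsv", sep="\t", index=False)
    chip_fc = dists[("FC", "H4K5ac")]
    igg_fc = dists[("FC", "IgG")]
    delta = coverage.enrichment_delta(chip_fc, igg_fc)
    summary["classification"] = {
        "chip_genic_pct": round(chip_fc.genic_pct, 1),
        "igg_genic_pct": round(igg_fc.genic_pct, 1),
        "delta_genic_pct": round(delta.delta_genic_pct, 1),
        "delta_genic_reads": delta.delta_genic_reads,
    }

    # --- profile ------------------------------------------------------
    window, bin_bp = cfg["profile"]["window"], cfg["profile"]["bin_bp"]
    depths = {key: coverage.per_gene_depth(rs, genes, window)
              for key, rs in study.readsets.items()}
    profiles = {}
    for key, dep in depths.items():
        profiles[key] = coverage.tss_profile(study.readsets[key], genes, window, bin_bp, depths=dep)
    prof_df = pd.DataFrame({"offset": profiles[("FC", "H4K5ac")].offsets})
    for (group, antibody), p in sorted(profiles.items()):
        prof_df[f"{group}_{antibody}"] = p.values
    prof_df.to_csv(outdir / "tss_profiles.tsv", sep="\t", index=False)
    chip_profile = profiles[("FC", "H4K5ac")]
    summary["profile"] = {
        "promoter_peak_offset": round(chip_profile.peak_offset(-1500, -300), 1),
        "cds_peak_offset": round(chip_profile.peak_offset(300, 1700), 1),
    }
    coverage.write_track(study.readsets[("FC", "H4K5ac")], outdir / "FC_H4K5ac.bedgraph")

    # --- expression / associate --------------------------------------
    ecfg = cfg["expression"]
    table = expression.ExpressionTable(
        study.expression,
        log2_transformed=ecfg["log2_transformed"],
        n_bins=ecfg["n_bins"],
        expressed_quantile=ecfg["expressed_quantile"],
    )
    table.write_tsv(outdir / "expression.tsv")
    scores = {group: coverage.gene_scores(study.readsets[(group, "H4K5ac")], genes, promoter_bp)
              for group in ("FC", "Control")}
    for group, sc in scores.items():
        sc.to_csv(outdir / f"gene_scores_{group}.tsv", sep="\t")
    assoc = expression.expression_acetylation_association(scores["FC"], table)
    summary["association"] = {
        "spearman_rho_promoter": round(assoc.rho_promoter, 3),
        "spearman_rho_window": round(assoc.rho_window, 3),
        "n_genes": assoc.n_genes,
    }

    # --- cluster ------------------------------------------------------
    ccfg = cfg["cluster"]
    matrix = profile_clustering.profile_matrix(
        study.readsets[("FC", "H4K5ac")], genes, ccfg["window"], ccfg["bin_bp"],
        scale=ccfg["scaling"], depths=depths[("FC", "H4K5ac")],
    )
    assignment = profile_clustering.kmeans_profiles(
        matrix, k=ccfg["k"], seed=cfg["seed"], restarts=ccfg["restarts"]
    )
    assignment.labels.rename("cluster").to_csv(outdir / "clusters.tsv", sep="\t")
    assignment.centroids.to_csv(outdir / "cluster_centroids.tsv", sep="\t")
    contrib = profile_clustering.contribution_crosstab(assignment, table.decile)
    contrib.to_csv(outdir / "cluster_by_expression.tsv", sep="\t")
    summary["cluster"] = {"k": assignment.k, "inertia": round(assignment.inertia, 4),
                          "semantic": assignment.semantic}

    # --- tfbs ---------------------------------------------------------
    tcfg = cfg["tfbs"]
    tf_depths = depths[("FC", "H4K5ac")]
    curves = tfbs_position.positional_curves(
        genes, tf_depths, study.tfbs, table.expressed,
        promoter_bp=tcfg["promoter_bp"], step_bp=tcfg["step_bp"],
        min_depth=tcfg["min_depth"],
    )
    curves.smoothed(tcfg["smooth_width"]).to_frame().to_csv(
        outdir / "tfbs_positional_curves.tsv", sep="\t", index=False
    )
    cond = tfbs_position.conditional_profiles(
        genes, tf_depths, study.tfbs, anchors=tuple(tcfg["anchors"]),
        tolerance_bp=tcfg["tolerance_bp"], no_tfbs_within=tcfg["no_tfbs_within"],
    )
    cond_df = pd.DataFrame({"offset": next(iter(cond.values())).offsets})
    for name, p in cond.items():
        cond_df[name] = p.values
    cond_df.to_csv(outdir / "tfbs_conditional_profiles.tsv", sep="\t", index=False)
    categories = tfbs_position.categorize_tfbs(
        genes, study.tfbs, promoter_bp=tcfg["promoter_bp"], proximal_bp=tcfg["proximal_bp"]
    )
    crosstab = profile_clustering.contribution_crosstab(assignment, categories)
    crosstab.to_csv(outdir / "cluster_by_tfbs.tsv", sep="\t")
    summary["tfbs"] = {"category_counts": categories.value_counts().to_dict()}

    # --- select -------------------------------------------------------
    scfg = cfg["select"]
    threshold = gene_selection.derive_threshold(scores["FC"], mode=scfg["mode"],
                                                manual_value=scfg.get("up"))
    above_fc = gene_selection.above_average_genes(scores["FC"], threshold)
    above_ctrl = gene_selection.above_average_genes(scores["Control"], threshold)
    diff = gene_selection.differential_by_criteria(
        scores["FC"], scores["Control"], up=scfg["up"], down=scfg["down"]
    )
    report = gene_selection.overlap_report({"FC": above_fc, "Control": above_ctrl})
    report.write_json(outdir / "overlap.json")
    gene_selection.write_gene_set(diff, outdir / "differential_genes.txt")
    planted = set(study.truth.planted)
    recovered = diff & planted
    summary["select"] = {
        "threshold": threshold,
        "n_above_FC": len(above_fc),
        "n_above_Control": len(above_ctrl),
        "n_differential": len(diff),
        "n_planted": len(planted),
        "sensitivity": round(len(recovered) / len(planted), 3) if planted else None,
        "false_positive_fraction": round(len(diff - planted) / len(diff), 3) if diff else None,
    }

    (outdir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (outdir / "config_used.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    logger.info("pipeline complete: %s", outdir)
    return summary
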