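# acetylscan

Genome-wide analysis of histone-acetylation ChIP-seq around transcription
start sites, built for studies that ask how an active-chromatin mark (such
as H4K5ac or H4K12ac in hippocampus after contextual fear conditioning)
relates to gene expression, transcription-factor binding sites, and
treatment-specific differential enrichment.

## What it computes

Given aligned ChIP-seq reads (BED/SAM), gene annotations (BED/GTF), an
expression table (TSV) and TFBS annotations (TSV/BED), the package provides:

* **Read classification** — each read is assigned by ≥1 bp overlap to the
  promoter (a fixed window, default 5 kb, upstream of the TSS), the gene
  body ("CDS", TSS to TTS), or intergenic space. A read spanning the TSS
  counts toward both promoter and body, so category percentages may sum
  above 100.
* **TSS metagene profiles** — strand-oriented base-level depth, binned
  (default 10 bp) and averaged over genes across ±*w* of the TSS.
* **Acetylation–expression association** — expression intensities are
  quantile-normalized, genes ranked into equal deciles, and Spearman's ρ
  computed between mean expression and promoter read counts, with
  per-decile mean profiles.
* **Profile clustering** — per-gene ±2 kb profiles, unit-sum scaled, are
  clustered with seeded k-means (k = 5 by default); contribution tables
  give each stratum's cluster composition.
* **TFBS positional analysis** — per-position percentage of expressed genes
  acetylated with vs. without a TFBS at that position (0–2 kb upstream,
  10 bp steps, running-median smoothing), metagene profiles conditioned on
  TFBS location classes, and an exhaustive gene categorization by promoter
  TFBS content relative to a 150 bp proximal cutoff.
* **Criteria-based selection** — "above average" genes (promoter reads
  strictly above the dataset mean rounded up to the nearest 10; a mean of
  45 yields a threshold of 50), the differential rule (> 50 reads in the
  treated group and ≤ 40 in controls), Venn-style overlap reports, and
  annotation of external peak-caller output (BED / MACS xls / SICER) by
  summit distance to the nearest TSS.
* **Enrichment & validation statistics** — upper-tail hypergeometric
  gene-set enrichment with Benjamini–Hochberg adjustment, and
  comparative-Cp qPCR fold changes (2^(mean control ΔCp − ΔCp), Welch
  t-test on ΔCp).
* **A seeded synthetic-data generator** — bimodal TSS-anchored signal
  (promoter mode −800 bp, gene-body mode +1000 bp), read counts coupled to
  expression rank, near-uniform IgG background, optional TFBS-dependent
  amplitude modulation, and planted group-specific differential genes, so
  the whole pipeline is testable end to end without any download.

## Worked example

Run the full pipeline on the default synthetic study (2,000 genes, four
samples: treated/control × signal antibody/IgG):

```bash
acetylscan run --out demo --seed 1
```

The printed report (also written to `demo/report.json`) includes:

```
"association":    {"spearman_rho_promoter": 0.628, "spearman_rho_window": 0.744}
"profile":        {"promoter_peak_offset": -807.2, "cds_peak_offset": 1002.6}
"classification": {"chip_genic_pct": 94.6, "igg_genic_pct": 54.4, "delta_genic_pct": 40.2}
"select":         {"threshold": 40, "n_differential": 91,
                   "sensitivity": 0.88, "false_positive_fraction": 0.033}
```

Reading: promoter acetylation correlates with expression (ρ ≈ 0.63 at the
gene level); the metagene profile recovers the generator's signal modes
(−800 bp promoter, +1 kb gene body) to within ~10 bp; ChIP reads are
40 percentage points more genic than the mock-IP background; and the
differential rule (> 50 treated / ≤ 40 control promoter reads) recovers 88
of the 100 planted hyperacetylated genes with 3 false positives. Stage
tables (classification, profiles, scores, clusters, TFBS curves, overlaps)
are written alongside as TSV/JSON.

Individual stages are available as subcommands (`simulate`, `classify`,
`profile`, `cluster`, `select`, `summary`) and, for scripting, as plain
library functions (see `acetylscan/__init__.py` for the public surface).

## Layout

```
src/acetylscan/
  genome_model.py        annotations, coordinate conventions, readers/writers
  coverage.py            read classification, metagene profiles, gene scores, tracks
  expression.py          quantile normalization, expression bins, association
  profile_clustering.py  k-means profile clustering, contribution tables
  tfbs_position.py       positional TFBS-acetylation analysis
  gene_selection.py      threshold/differential selection, overlaps, peak adapters
  enrichment_validation.py  hypergeometric enrichment, qPCR fold changes
  synthetic_data.py      seeded study generator with ground truth
  pipeline.py, cli.py    orchestration, config, report, command line
docs/methods.md          model, parameter and design notes
```
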