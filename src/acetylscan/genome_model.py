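"""Gene and TFBS annotation model with strand-aware TSS arithmetic.

All coordinates are 0-based half-open internally (BED convention). GTF input,
which is 1-based inclusive, is converted on read. The transcription start
site (TSS) of a plus-strand gene is its ``start``; for a minus-strand gene it
is ``end - 1`` (the last covered base). Every positional quantity downstream
(promoter windows, metagene offsets, TFBS offsets) is expressed relative to
the TSS in the gene's own orientation: negative offsets are upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "TfbsSite",
    "load_annotations",
    "write_annotations",
    "load_tfbs",
    "write_tfbs",
    "promoter_interval",
    "tss_relative_offset",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative interval start: {self.start}")
        if self.end < self.start:
            raise ValueError(f"interval end < start: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body anchoring all TSS-relative arithmetic.

    ``start``/``end`` delimit the gene body (the "CDS" in the loose sense of
    everything between TSS and TTS, introns included). ``tss`` and ``tts``
    are derived from the strand and are single base positions.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid body [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class TfbsSite:
    """A transcription factor binding site at a TSS-relative offset.

    ``offset`` is strand-aware: negative means upstream of the gene's TSS.
    ``genomic_pos`` is kept when the site came from genomic (BED) input.
    """

    gene_id: str
    offset: int
    genomic_pos: int | None = None


def promoter_interval(gene: GeneAnnotation, upstream_bp: int) -> GenomicInterval:
    """Strand-aware promoter window immediately upstream of the TSS.

    The interval has length ``min(upstream_bp, distance to chromosome
    start)``; it is clipped at coordinate 0 and may be empty for a
    plus-strand gene whose TSS sits at the chromosome edge.
    """
    if upstream_bp <= 0:
        raise ValueError("upstream_bp must be positive")
    if gene.strand == "+":
        return GenomicInterval(
            gene.chrom, max(0, gene.tss - upstream_bp), gene.tss, "+"
        )
    return GenomicInterval(gene.chrom, gene.tss + 1, gene.tss + 1 + upstream_bp, "-")


def tss_relative_offset(gene: GeneAnnotation, genomic_pos: int, chrom: str | None = None) -> int:
    """Signed offset of a genomic base from the gene's TSS.

    Negative offsets are upstream in the gene's orientation; the TSS itself
    maps to 0.
    """
    if chrom is not None and chrom != gene.chrom:
        raise ValueError(
            f"chromosome mismatch: position on {chrom}, gene {gene.gene_id} on {gene.chrom}"
        )
    if gene.strand == "+":
        return genomic_pos - gene.tss
    return gene.tss - genomic_pos


# ---------------------------------------------------------------------------
# readers / writers


def _parse_bed_line(line: str, lineno: int) -> GeneAnnotation:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 4:
        raise ValueError(f"line {lineno}: BED gene records need >= 4 columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    strand = fields[5] if len(fields) >= 6 else "+"
    try:
        return GeneAnnotation(fields[3], fields[0], strand, start, end)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            out[key] = value.strip().strip('"')
    return out


def _iter_gtf(path: Path) -> Iterable[GeneAnnotation]:
    transcripts: list[GeneAnnotation] = []
    gene_rows: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"line {lineno}: GTF needs 9 columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature not in ("transcript", "gene"):
                continue
            parsed = _parse_gtf_attributes(attrs)
            gene_id = parsed.get("gene_id") or parsed.get("transcript_id")
            if gene_id is None:
                raise ValueError(f"line {lineno}: missing gene_id/transcript_id")
            try:
                # GTF is 1-based inclusive -> half-open
                rec = GeneAnnotation(gene_id, chrom, strand, int(start) - 1, int(end))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            (transcripts if feature == "transcript" else gene_rows).append(rec)
    return transcripts if transcripts else gene_rows


def load_annotations(path: str | Path, format: str | None = None) -> list[GeneAnnotation]:
    """Load gene annotations from BED4/6/12 or GTF.

    Duplicate gene_ids are resolved to the longest transcript (ties broken by
    smaller start, then input order). Returns a list sorted by (chrom, start).
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "GTF" if suffix in (".gtf", ".gff") else "BED"
    format = format.upper()

    records: list[GeneAnnotation] = []
    if format == "BED":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                records.append(_parse_bed_line(line, lineno))
    elif format == "GTF":
        records = list(_iter_gtf(path))
    else:
        raise ValueError(f"unknown annotation format: {format}")

    if not records:
        logger.warning("no gene records in %s", path)
        return []

    best: dict[str, GeneAnnotation] = {}
    for rec in records:
        prev = best.get(rec.gene_id)
        if prev is None or (rec.length, -rec.start) > (prev.length, -prev.start):
            best[rec.gene_id] = rec
    genes = sorted(best.values(), key=lambda g: (g.chrom, g.start, g.gene_id))
    logger.info("loaded %d genes (%d records) from %s", len(genes), len(records), path)
    return genes


def write_annotations(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write genes as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def load_tfbs(
    path: str | Path,
    genes: Sequence[GeneAnnotation] | None = None,
    promoter_bp: int = 2000,
    format: str | None = None,
) -> list[TfbsSite]:
    """Load TFBS as gene_id/offset TSV, or genomic BED mapped onto promoters.

    For BED input each site midpoint is assigned to every gene whose
    ``promoter_bp`` upstream window contains it, with the offset computed in
    that gene's orientation (requires ``genes``).
    """
    path = Path(path)
    if format is None:
        format = "BED" if path.suffix.lower() == ".bed" else "TSV"
    format = format.upper()
    sites: list[TfbsSite] = []
    if format == "TSV":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("gene_id"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"line {lineno}: TFBS TSV needs gene_id<TAB>offset")
                try:
                    sites.append(TfbsSite(fields[0], int(fields[1])))
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: non-integer offset") from exc
    elif format == "BED":
        if genes is None:
            raise ValueError("genomic TFBS (BED) input requires gene annotations")
        promoters = [(g, promoter_interval(g, promoter_bp)) for g in genes]
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "#")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 3:
                    raise ValueError(f"line {lineno}: BED needs >= 3 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                mid = (start + end) // 2
                for g, prom in promoters:
                    if prom.chrom == chrom and prom.start <= mid < prom.end:
                        sites.append(
                            TfbsSite(g.gene_id, tss_relative_offset(g, mid), mid)
                        )
    else:
        raise ValueError(f"unknown TFBS format: {format}")
    logger.info("loaded %d TFBS sites from %s", len(sites), path)
    return sites


def write_tfbs(sites: Sequence[TfbsSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\toffset\n")
        for s in sites:
            fh.write(f"{s.gene_id}\t{s.offset}\n")
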