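"""SNP-to-gene assignment and candidate-gene reporting.

A SNP belongs to a gene if its position falls within the gene's annotated
span (UTRs + coding + introns) extended by ``flank_bp`` on both sides —
capturing upstream/downstream regulatory regions. The flank distance is a
required, surfaced parameter (default 5,000 bp): annotation sources differ
on what "upstream" means and no single constant deserves to be hidden.

Coordinates are 1-based inclusive internally; BED input (0-based half-open)
is converted on read.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .dataset import MarkerRecord
from .scan import ScanResult

DEFAULT_FLANK_BP = 5_000


class AnnotationFormatError(ValueError):
    """Malformed annotation file (bad coordinates or column counts)."""


@dataclass(frozen=True)
class GeneInterval:
    """Annotated gene span, 1-based inclusive."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start_bp} > end {self.end_bp}"
            )


def read_annotation(path: str | os.PathLike, dialect: str = "bed") -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open) or the package's
    1-based TSV dialect ("tsv1": gene_id, chrom, start_bp, end_bp, strand
    with a header row). Intervals are returned sorted by (chrom, start)."""
    if dialect not in ("bed", "tsv1"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if dialect == "tsv1" and ln == 1 and line.startswith("gene_id"):
                continue
            parts = line.split()
            try:
                if dialect == "bed":
                    if len(parts) < 4:
                        raise AnnotationFormatError(
                            f"{path}: line {ln}: BED needs >= 4 columns"
                        )
                    chrom, start0, end0, gene_id = parts[:4]
                    strand = parts[5] if len(parts) >= 6 else "+"
                    start_bp, end_bp = int(start0) + 1, int(end0)
                else:
                    if len(parts) != 5:
                        raise AnnotationFormatError(
                            f"{path}: line {ln}: tsv1 needs 5 columns"
                        )
                    gene_id, chrom, start, end, strand = parts
                    start_bp, end_bp = int(start), int(end)
                genes.append(GeneInterval(gene_id, chrom, start_bp, end_bp, strand))
            except ValueError as exc:
                raise AnnotationFormatError(f"{path}: line {ln}: {exc}") from exc
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise AnnotationFormatError(f"{path}: duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)
    genes.sort(key=lambda g: (g.chrom, g.start_bp, g.gene_id))
    return genes


def write_annotation(
    genes: list[GeneInterval], path: str | os.PathLike, dialect: str = "tsv1"
) -> None:
    with open(path, "w") as fh:
        if dialect == "tsv1":
            fh.write("gene_id\tchrom\tstart_bp\tend_bp\tstrand\n")
            for g in genes:
                fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start_bp}\t{g.end_bp}\t{g.strand}\n")
        elif dialect == "bed":
            for g in genes:
                fh.write(f"{g.chrom}\t{g.start_bp - 1}\t{g.end_bp}\t{g.gene_id}\t0\t{g.strand}\n")
        else:
            raise ValueError(f"unknown annotation dialect {dialect!r}")


def assign_snps_to_genes(
    markers: list[MarkerRecord],
    annotation: list[GeneInterval],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> dict[str, list[str]]:
    """Map each mapped marker id to the (sorted) gene ids whose flanked span
    contains it: pos in [start - flank, end + flank], same chromosome.
    Multi-gene assignment is allowed; unassigned markers map to []."""
    if flank_bp < 0:
        raise ValueError(f"flank_bp must be >= 0, got {flank_bp}")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in annotation:
        lo = max(1, g.start_bp - flank_bp)
        hi = g.end_bp + flank_bp + 1  # intervaltree is half-open
        trees[g.chrom].addi(lo, hi, g.gene_id)
    out: dict[str, list[str]] = {}
    for m in markers:
        if m.is_unmapped:
            continue
        hits = trees[m.chrom][m.pos_bp] if m.chrom in trees else ()
        out[m.marker_id] = sorted(iv.data for iv in hits)
    return out


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str
    outlier_snp_ids: tuple[str, ...]
    n_outlier_snps: int
    max_contiguous_run: int


@dataclass
class CandidateGeneReport:
    """Genes hit by outlier SNPs, plus the flagged SNPs with no gene."""

    genes: list[CandidateGene]
    intergenic_snp_ids: list[str]
    flank_bp: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "n_outlier_snps": [g.n_outlier_snps for g in self.genes],
                "max_contiguous_run": [g.max_contiguous_run for g in self.genes],
                "outlier_snp_ids": [",".join(g.outlier_snp_ids) for g in self.genes],
            }
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# flank_bp={self.flank_bp}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    def write_intergenic_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame({"marker_id": self.intergenic_snp_ids}).to_csv(
            path, sep="\t", index=False
        )


def candidate_gene_report(
    scan: ScanResult,
    assignment: dict[str, list[str]],
    markers: list[MarkerRecord],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> CandidateGeneReport:
    """Per-gene outlier counts and longest contiguous-outlier runs.

    A run for gene g is a maximal stretch of markers, consecutive in genome
    map order among ALL markers, that are each outlier-flagged and assigned
    to g; any unflagged marker (or a flagged marker outside g) breaks it.
    Flagged SNPs assigned to no gene are collected as intergenic, so per-gene
    distinct flagged SNPs plus intergenic flagged SNPs account for every
    flagged SNP exactly once per gene it belongs to.
    """
    if len(markers) != len(scan.outlier_flags):
        raise ValueError("scan result and marker list are misaligned")
    per_gene_snps: dict[str, list[str]] = defaultdict(list)
    per_gene_best_run: dict[str, int] = defaultdict(int)
    current_run: dict[str, int] = {}
    intergenic: list[str] = []

    for idx, m in enumerate(markers):
        flagged = bool(scan.outlier_flags[idx])
        genes_here = assignment.get(m.marker_id, []) if flagged else []
        if flagged:
            if genes_here:
                for g in genes_here:
                    per_gene_snps[g].append(m.marker_id)
            else:
                intergenic.append(m.marker_id)
        # extend or break runs
        nxt: dict[str, int] = {}
        for g in genes_here:
            nxt[g] = current_run.get(g, 0) + 1
            if nxt[g] > per_gene_best_run[g]:
                per_gene_best_run[g] = nxt[g]
        current_run = nxt

    genes = [
        CandidateGene(
            gene_id=g,
            outlier_snp_ids=tuple(snps),
            n_outlier_snps=len(snps),
            max_contiguous_run=per_gene_best_run[g],
        )
        for g, snps in per_gene_snps.items()
    ]
    genes.sort(key=lambda c: (-c.n_outlier_snps, c.gene_id))
    return CandidateGeneReport(genes=genes, intergenic_snp_ids=intergenic,
                               flank_bp=flank_bp)
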