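"""Model/results interface to the selection scan.

:class:`SelectionScan` bundles a genotype dataset with the analysis
configuration (grouping, QC thresholds, outlier quantiles, optional gene
annotation); :meth:`SelectionScan.fit` runs QC, the per-SNP Fst ANOVA, the
empirical-quantile outlier scan and (when annotation is present) the
candidate-gene report, returning a :class:`SelectionScanResults` that holds
the estimates and renders a text summary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .dataset import GenotypeDataset, summarize_dataset
from .fst import FstTable, Grouping, fst_scan
from .genes import (DEFAULT_FLANK_BP, CandidateGeneReport, GeneInterval,
                    assign_snps_to_genes, candidate_gene_report)
from .io import read_ped_map
from .pca import PCAResult, pca_dataset
from .qc import QCConfig, QCReport, run_qc
from .scan import ScanConfig, ScanResult, select_outliers


class SelectionScan:
    """Genome-wide Fst outlier scan model.

    Parameters
    ----------
    dataset
        Genotypes with breed labels; QC is applied inside :meth:`fit`.
    grouping
        Breed -> population assignment; defaults to one population per breed.
    qc_config, scan_config
        Filtering thresholds and outlier quantiles.
    annotation, flank_bp
        Optional gene intervals for candidate-gene reporting; SNPs within
        ``flank_bp`` of a gene span belong to it.
    """

    def __init__(
        self,
        dataset: GenotypeDataset,
        grouping: Grouping | None = None,
        qc_config: QCConfig | None = None,
        scan_config: ScanConfig | None = None,
        annotation: list[GeneInterval] | None = None,
        flank_bp: int = DEFAULT_FLANK_BP,
    ):
        self.dataset = dataset
        self.grouping = grouping or Grouping.all_populations(dataset.breeds)
        self.qc_config = qc_config or QCConfig()
        self.scan_config = scan_config or ScanConfig()
        self.annotation = annotation
        self.flank_bp = flank_bp

    @classmethod
    def from_ped_map(cls, ped_path: str | os.PathLike,
                     map_path: str | os.PathLike, **kwargs) -> "SelectionScan":
        return cls(read_ped_map(ped_path, map_path), **kwargs)

    def fit(self) -> "SelectionScanResults":
        filtered, qc_report = run_qc(self.dataset, self.qc_config)
        table = fst_scan(filtered, self.grouping)
        scan = select_outliers(table, self.scan_config)
        genes = None
        if self.annotation is not None:
            assignment = assign_snps_to_genes(filtered.markers, self.annotation,
                                              self.flank_bp)
            genes = candidate_gene_report(scan, assignment, filtered.markers,
                                          self.flank_bp)
        return SelectionScanResults(
            model=self, filtered=filtered, qc_report=qc_report,
            fst_table=table, scan=scan, candidate_genes=genes,
        )


@dataclass
class SelectionScanResults:
    """Fitted scan: QC report, per-SNP Fst table, thresholds, outliers."""

    model: SelectionScan
    filtered: GenotypeDataset
    qc_report: QCReport
    fst_table: FstTable
    scan: ScanResult
    candidate_genes: CandidateGeneReport | None

    @property
    def mean_fst(self) -> float:
        return self.fst_table.mean_fst

    @property
    def sd_fst(self) -> float:
        return self.fst_table.sd_fst

    @property
    def thresholds(self) -> dict[float, float]:
        return self.scan.thresholds

    @property
    def n_outliers(self) -> int:
        return self.scan.n_outliers

    def outlier_marker_ids(self) -> list[str]:
        return list(self.fst_table.marker_ids[self.scan.outlier_flags])

    def pca(self, k: int = 10) -> PCAResult:
        """Population-structure PCA on the QC-passed genotypes."""
        return pca_dataset(self.filtered, k=k)

    def summary(self) -> str:
        ds = summarize_dataset(self.model.dataset)
        qc = self.qc_report
        lines = [
            "Genome-wide Fst selection scan",
            "==============================",
            f"grouping:        {self.fst_table.grouping_name} "
            f"({self.model.grouping.n_pops} populations)",
            f"individuals:     {ds.n_individuals}",
            f"markers in:      {qc.n_input}",
            f"  - unmapped:    {qc.n_removed_unmapped}",
            f"  - MAF < {self.model.qc_config.maf_threshold:g}:  "
            f"{qc.n_removed_maf}",
            f"  - call rate < {self.model.qc_config.call_rate_threshold:g}: "
            f"{qc.n_removed_callrate}",
            f"markers kept:    {qc.n_output}",
            f"defined Fst:     {self.scan.n_defined}",
            f"mean Fst (sd):   {self.mean_fst:.4f} ({self.sd_fst:.4f})",
            f"multilocus Fst:  {self.fst_table.ratio_of_sums_fst():.4f}",
        ]
        for q, thr in sorted(self.thresholds.items()):
            lines.append(f"threshold q={q:g}:  {thr:.4f}")
        lines.append(f"outliers (q={self.scan.selection_quantile:g}): "
                     f"{self.n_outliers}")
        if self.candidate_genes is not None:
            lines.append(f"candidate genes: {len(self.candidate_genes.genes)} "
                         f"(flank {self.candidate_genes.flank_bp} bp)")
            top = self.candidate_genes.genes[:5]
            for g in top:
                lines.append(
                    f"  {g.gene_id}: {g.n_outlier_snps} outlier SNPs, "
                    f"longest run {g.max_contiguous_run}"
                )
        return "\n".join(lines)
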