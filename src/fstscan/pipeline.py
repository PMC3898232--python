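"""End-to-end orchestration: load/simulate -> QC -> Fst scans -> outliers ->
gene report -> PCA -> distance correlation, from one YAML-able config.

Every stage writes its TSV outputs under the output directory and the run
closes with a JSON manifest (config echo, seed, row counts, thresholds).
Outputs are deterministic given config + seed: float formatting is fixed
and the manifest carries no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .dataset import GenotypeDataset, summarize_dataset
from .fst import Grouping, fst_scan, merge_grouping
from .genes import (DEFAULT_FLANK_BP, assign_snps_to_genes,
                    candidate_gene_report, read_annotation)
from .io import read_ped_map
from .pca import pca_dataset
from .qc import QCConfig, run_qc
from .scan import (ScanConfig, fst_distance_correlation, per_chromosome_track,
                   scan_frame, select_outliers)
from .simulate import SimConfig, make_annotation_fixture, simulate_dataset

logger = logging.getLogger("fstscan")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Configuration for one full run.

    Either ``ped_path``/``map_path`` or an inline ``simulate`` block must be
    given. ``groupings`` maps analysis names to breed -> group-name maps;
    the all-breeds ALLPOP analysis always runs.
    """

    output_dir: str
    ped_path: str | None = None
    map_path: str | None = None
    simulate: SimConfig | None = None
    qc: QCConfig = field(default_factory=QCConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    groupings: dict[str, dict[str, str]] = field(default_factory=dict)
    annotation_path: str | None = None
    annotation_dialect: str = "bed"
    #: use the simulator's tiled annotation fixture instead of a file
    annotation_fixture_fraction: float | None = None
    flank_bp: int = DEFAULT_FLANK_BP
    pcs: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            for key in ("pop_names", "pop_sizes", "group_split",
                        "ancestral_freq_range"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            if "chrom_layout" in sim:
                sim["chrom_layout"] = tuple(
                    (str(c), int(l)) for c, l in sim["chrom_layout"]
                )
            raw["simulate"] = SimConfig(**sim)
        if "qc" in raw and isinstance(raw["qc"], Mapping):
            raw["qc"] = QCConfig(**raw["qc"])
        if "scan" in raw and isinstance(raw["scan"], Mapping):
            scan = dict(raw["scan"])
            if "quantiles" in scan:
                scan["quantiles"] = tuple(scan["quantiles"])
            raw["scan"] = ScanConfig(**scan)
        return cls(**raw)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return inner
    return wrap


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage in fixed order; return (and write) the manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict[str, Any] = {
        "fstscan_version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
    }
    try:
        dataset, truth = _load_stage(config, outdir)
        manifest["input"] = {
            "n_individuals": dataset.n_individuals,
            "n_markers": dataset.n_markers,
        }
        filtered, qc_report = _qc_stage(config, dataset, outdir)
        manifest["qc"] = {
            "n_input": qc_report.n_input,
            "n_removed_unmapped": qc_report.n_removed_unmapped,
            "n_removed_maf": qc_report.n_removed_maf,
            "n_removed_callrate": qc_report.n_removed_callrate,
            "n_output": qc_report.n_output,
        }

        annotation = _annotation_stage(config, filtered)
        assignment = None
        if annotation is not None:
            assignment = assign_snps_to_genes(filtered.markers, annotation,
                                              config.flank_bp)

        breeds = filtered.breeds
        analyses: list[Grouping] = [Grouping.all_populations(breeds)]
        for name, gmap in config.groupings.items():
            analyses.append(merge_grouping(breeds, gmap, name=name))

        manifest["analyses"] = {}
        for grouping in analyses:
            manifest["analyses"][grouping.name] = _analysis_stage(
                config, filtered, grouping, assignment, outdir
            )

        manifest["pca"] = _pca_stage(config, filtered, outdir)
        logger.info("pipeline complete")
    finally:
        logger.removeHandler(handler)
        handler.close()

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


@_stage("load")
def _load_stage(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        dataset, truth = simulate_dataset(config.simulate)
        truth.write_tsv(outdir / "sim_truth.tsv")
    elif config.ped_path and config.map_path:
        dataset, truth = read_ped_map(config.ped_path, config.map_path), None
    else:
        raise ValueError("config needs ped_path+map_path or a simulate block")
    summary = summarize_dataset(dataset)
    logger.info("loaded %d individuals x %d markers",
                summary.n_individuals, summary.n_markers)
    return dataset, truth


@_stage("qc")
def _qc_stage(config: PipelineConfig, dataset: GenotypeDataset, outdir: Path):
    filtered, report = run_qc(dataset, config.qc)
    report.write_tsv(outdir / "qc_removed.tsv")
    (outdir / "qc_summary.txt").write_text(report.summary() + "\n")
    logger.info("QC: %s -> %s markers", report.n_input, report.n_output)
    return filtered, report


@_stage("annotation")
def _annotation_stage(config: PipelineConfig, dataset: GenotypeDataset):
    if config.annotation_path:
        return read_annotation(config.annotation_path, config.annotation_dialect)
    if config.annotation_fixture_fraction is not None:
        return make_annotation_fixture(dataset.markers,
                                       fraction=config.annotation_fixture_fraction)
    return None


@_stage("analysis")
def _analysis_stage(config, dataset, grouping, assignment, outdir: Path):
    table = fst_scan(dataset, grouping)
    result = select_outliers(table, config.scan)
    tag = grouping.name
    table.write_tsv(outdir / f"fst_{tag}.tsv")
    scan_frame(table, result).to_csv(outdir / f"scan_{tag}.tsv", sep="\t",
                                     index=False, float_format="%.10g")
    per_chromosome_track(table, result).to_csv(
        outdir / f"track_{tag}.tsv", sep="\t", index=False, float_format="%.10g"
    )
    entry: dict[str, Any] = {
        "n_markers": len(table),
        "n_defined": result.n_defined,
        "mean_fst": table.mean_fst,
        "sd_fst": table.sd_fst,
        "ratio_of_sums_fst": table.ratio_of_sums_fst(),
        "thresholds": {f"{q:g}": t for q, t in result.thresholds.items()},
        "n_outliers": result.n_outliers,
    }
    if assignment is not None:
        report = candidate_gene_report(result, assignment, dataset.markers,
                                       config.flank_bp)
        report.write_tsv(outdir / f"genes_{tag}.tsv")
        report.write_intergenic_tsv(outdir / f"intergenic_{tag}.tsv")
        entry["n_candidate_genes"] = len(report.genes)
        entry["n_intergenic_outliers"] = len(report.intergenic_snp_ids)
    if grouping.name == "ALLPOP":
        corr = fst_distance_correlation(table, config.scan, seed=config.seed)
        corr.to_frame().to_csv(outdir / "fst_distance_correlation.tsv",
                               sep="\t", index=False, float_format="%.10g")
    logger.info("analysis %s: %d outliers of %d defined",
                tag, result.n_outliers, result.n_defined)
    return entry


@_stage("pca")
def _pca_stage(config: PipelineConfig, dataset: GenotypeDataset, outdir: Path):
    result = pca_dataset(dataset, k=config.pcs)
    result.to_frame(dataset).to_csv(outdir / "pca_scores.tsv", sep="\t",
                                    index=False, float_format="%.10g")
    with open(outdir / "pca_variance.tsv", "w") as fh:
        fh.write("component\tvariance_fraction\n")
        for j, v in enumerate(result.variance_fraction, start=1):
            fh.write(f"PC{j}\t{v:.10g}\n")
    logger.info("PCA: %d components, PC1 %.2f%%", result.k,
                100 * result.variance_fraction[0])
    return {
        "k": result.k,
        "variance_fraction": [float(v) for v in result.variance_fraction],
    }
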