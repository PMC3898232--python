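"""Sequential marker quality control.

Three filters, applied in order, each counted on the survivors of the
previous step: (1) drop unmapped markers; (2) drop markers with pooled minor
allele frequency strictly below the MAF threshold; (3) drop markers
genotyped on strictly less than the call-rate threshold of all individuals.
Boundary values (MAF exactly at threshold, call rate exactly at threshold)
are retained. Individuals are never removed.

MAF is pooled across all individuals regardless of breed: with f the
frequency of the counted allele among non-missing calls, MAF = min(f, 1-f).
Call rate is the fraction of all individuals (missing included in the
denominator) with a non-missing call.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset


@dataclass(frozen=True)
class QCConfig:
    maf_threshold: float = 0.05
    call_rate_threshold: float = 0.90
    drop_unmapped: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_threshold", "call_rate_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """Removal counts per sequential filter plus per-marker diagnostics.

    ``maf`` and ``call_rate`` are indexed like the *input* dataset's markers
    (MAF is NaN for markers with zero non-missing calls). ``removed_reason``
    holds "" for survivors, else "unmapped" / "low_maf" / "low_callrate".
    """

    n_input: int
    n_removed_unmapped: int
    n_removed_maf: int
    n_removed_callrate: int
    n_output: int
    maf: np.ndarray = field(repr=False)
    call_rate: np.ndarray = field(repr=False)
    removed_reason: np.ndarray = field(repr=False)
    marker_ids: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        expected = (
            self.n_input
            - self.n_removed_unmapped
            - self.n_removed_maf
            - self.n_removed_callrate
        )
        if self.n_output != expected:
            raise ValueError(
                f"inconsistent QC report: n_output {self.n_output} != {expected}"
            )

    def removed_frame(self) -> pd.DataFrame:
        """One row per removed marker with the removal reason."""
        rem = self.removed_reason != ""
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids[rem],
                "reason": self.removed_reason[rem],
                "maf": self.maf[rem],
                "call_rate": self.call_rate[rem],
            }
        )

    def summary(self) -> str:
        return (
            f"input markers:              {self.n_input}\n"
            f"removed, unmapped:          {self.n_removed_unmapped}\n"
            f"removed, MAF below cutoff:  {self.n_removed_maf}\n"
            f"removed, low call rate:     {self.n_removed_callrate}\n"
            f"markers retained:           {self.n_output}"
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.removed_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _pooled_maf(calls: np.ndarray) -> np.ndarray:
    """Pooled MAF per marker column; NaN where no calls are present."""
    present = calls != MISSING
    n_called = present.sum(axis=0)
    dose = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = dose / (2.0 * n_called)
    maf = np.minimum(f, 1.0 - f)
    maf[n_called == 0] = np.nan
    return maf


def compute_maf(dataset: GenotypeDataset, marker_index: int) -> float:
    """Pooled minor allele frequency at one marker, over non-missing calls.

    Raises ValueError if every call at the marker is missing.
    """
    col = dataset.calls[:, marker_index]
    present = col != MISSING
    n_called = int(present.sum())
    if n_called == 0:
        raise ValueError(
            f"MAF undefined for marker {dataset.markers[marker_index].marker_id}: "
            "all calls missing"
        )
    f = float(col[present].sum()) / (2.0 * n_called)
    return min(f, 1.0 - f)


def compute_call_rate(dataset: GenotypeDataset, marker_index: int) -> float:
    col = dataset.calls[:, marker_index]
    return float((col != MISSING).sum()) / dataset.n_individuals


def run_qc(
    dataset: GenotypeDataset, config: QCConfig | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the three sequential filters; return survivors and the report.

    Marker order is preserved among survivors. A fully-missing marker has
    undefined MAF; it passes the MAF stage and is removed at the call-rate
    stage (call rate 0).
    """
    if config is None:
        config = QCConfig()
    if dataset.n_markers == 0 or dataset.n_individuals == 0:
        raise ValueError("run_qc requires a non-empty dataset")

    n_input = dataset.n_markers
    maf = _pooled_maf(dataset.calls)
    call_rate = (dataset.calls != MISSING).sum(axis=0) / dataset.n_individuals
    reason = np.full(n_input, "", dtype=object)

    alive = np.ones(n_input, dtype=bool)

    if config.drop_unmapped:
        unmapped = np.array([m.is_unmapped for m in dataset.markers])
        reason[alive & unmapped] = "unmapped"
        alive &= ~unmapped
    n_removed_unmapped = int((reason == "unmapped").sum())

    low_maf = alive & (maf < config.maf_threshold)  # NaN compares False: passes
    reason[low_maf] = "low_maf"
    alive &= ~low_maf
    n_removed_maf = int(low_maf.sum())

    low_cr = alive & (call_rate < config.call_rate_threshold)
    reason[low_cr] = "low_callrate"
    alive &= ~low_cr
    n_removed_callrate = int(low_cr.sum())

    filtered = dataset.subset_markers(alive)
    report = QCReport(
        n_input=n_input,
        n_removed_unmapped=n_removed_unmapped,
        n_removed_maf=n_removed_maf,
        n_removed_callrate=n_removed_callrate,
        n_output=int(alive.sum()),
        maf=maf,
        call_rate=call_rate,
        removed_reason=reason,
        marker_ids=dataset.marker_ids(),
    )
    return filtered, report
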