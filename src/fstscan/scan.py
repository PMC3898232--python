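"""Empirical-quantile outlier detection on the genome-wide Fst distribution.

The threshold at quantile q over N defined per-locus values is the order
statistic of 1-based rank ceil(q*N) — an element of the value set, no
interpolation — and a locus is an outlier iff its value is *strictly*
greater than the threshold. With N distinct values this selects exactly
N - ceil(q*N) loci (e.g. 446 of 44,652 at q = 0.99). UNDEFINED loci are
excluded from the distribution and never flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fst import FstTable


@dataclass(frozen=True)
class ScanConfig:
    quantiles: tuple[float, ...] = (0.975, 0.99)
    selection_quantile: float = 0.99
    distance_bin_bp: int = 50_000
    max_distance_bp: int = 1_000_000
    max_pairs_per_bin: int = 10_000

    def __post_init__(self) -> None:
        for q in self.quantiles:
            if not 0.0 < q < 1.0:
                raise ValueError(f"quantile {q} outside (0, 1)")
        if self.selection_quantile not in self.quantiles:
            raise ValueError("selection_quantile must be one of quantiles")


def empirical_threshold(fst_values: np.ndarray, q: float) -> float:
    """Order statistic of rank ceil(q*N) (1-based) among the defined values."""
    values = np.asarray(fst_values, dtype=float)
    values = values[~np.isnan(values)]
    n = len(values)
    if n == 0:
        raise ValueError("empirical_threshold: no defined values")
    rank = math.ceil(q * n)
    rank = min(max(rank, 1), n)
    return float(np.partition(values, rank - 1)[rank - 1])


@dataclass
class ScanResult:
    """Quantile thresholds and per-marker outlier flags for one Fst table."""

    grouping_name: str
    thresholds: dict[float, float]
    selection_quantile: float
    outlier_flags: np.ndarray  # bool, aligned with the FstTable's markers
    n_defined: int

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_flags.sum())

    @property
    def selection_threshold(self) -> float:
        return self.thresholds[self.selection_quantile]


def select_outliers(table: FstTable, config: ScanConfig | None = None) -> ScanResult:
    """Thresholds for every configured quantile; flags at the selection one."""
    if config is None:
        config = ScanConfig()
    defined = table.defined_mask
    values = table.fst[defined]
    thresholds = {q: empirical_threshold(values, q) for q in config.quantiles}
    thr = thresholds[config.selection_quantile]
    flags = np.zeros(len(table), dtype=bool)
    flags[defined] = table.fst[defined] > thr
    return ScanResult(
        grouping_name=table.grouping_name,
        thresholds=thresholds,
        selection_quantile=config.selection_quantile,
        outlier_flags=flags,
        n_defined=int(defined.sum()),
    )


def scan_frame(table: FstTable, result: ScanResult) -> pd.DataFrame:
    """Per-marker table: fst plus an outlier column per threshold quantile."""
    df = pd.DataFrame(
        {
            "marker_id": table.marker_ids,
            "chrom": table.chrom,
            "pos_bp": table.pos_bp,
            "fst": table.fst,
        }
    )
    for q, thr in sorted(result.thresholds.items()):
        col = np.zeros(len(table), dtype=bool)
        d = table.defined_mask
        col[d] = table.fst[d] > thr
        df[f"outlier_q{q:g}"] = col
    df["outlier"] = result.outlier_flags
    return df


def per_chromosome_track(table: FstTable, result: ScanResult) -> pd.DataFrame:
    """Plot-ready per-chromosome records: position in Mb, fst, outlier flag.

    Mapped markers only, grouped by chromosome and ordered by position;
    threshold values are attached as constant columns so any plotting tool
    can draw the quantile lines.
    """
    mapped = (table.pos_bp > 0) & (table.chrom != "0") & (table.chrom != "")
    df = pd.DataFrame(
        {
            "chrom": table.chrom[mapped],
            "pos_mb": table.pos_bp[mapped] / 1e6,
            "marker_id": table.marker_ids[mapped],
            "fst": table.fst[mapped],
            "outlier": result.outlier_flags[mapped],
        }
    )
    for q, thr in sorted(result.thresholds.items()):
        df[f"threshold_q{q:g}"] = thr
    df = df.sort_values(["chrom", "pos_mb"], kind="stable").reset_index(drop=True)
    return df


@dataclass
class DistanceCorrelation:
    """Correlation of per-SNP Fst between same-chromosome pairs, by distance."""

    bin_low_bp: np.ndarray
    bin_high_bp: np.ndarray
    n_pairs: np.ndarray
    correlation: np.ndarray  # NaN for bins with < 10 pairs or no variance

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_bp": self.bin_low_bp,
                "bin_high_bp": self.bin_high_bp,
                "n_pairs": self.n_pairs,
                "correlation": self.correlation,
            }
        )


def fst_distance_correlation(
    table: FstTable,
    config: ScanConfig | None = None,
    seed: int = 0,
) -> DistanceCorrelation:
    """Fst correlation between same-chromosome SNP pairs as a function of
    marker distance.

    Pairs are enumerated per chromosome up to ``max_distance_bp`` apart,
    binned by separation, uniformly subsampled to ``max_pairs_per_bin`` with
    a generator seeded by ``seed``, and entered symmetrically into the
    correlation. Bins with fewer than 10 pairs are reported empty (NaN).
    """
    if config is None:
        config = ScanConfig()
    width = config.distance_bin_bp
    maxd = config.max_distance_bp
    n_bins = maxd // width
    rng = np.random.default_rng(seed)

    mapped = (table.pos_bp > 0) & (table.chrom != "0") & (table.chrom != "") \
        & table.defined_mask
    bin_x: list[list[np.ndarray]] = [[] for _ in range(n_bins)]
    bin_y: list[list[np.ndarray]] = [[] for _ in range(n_bins)]

    for chrom in pd.unique(table.chrom[mapped]):
        sel = mapped & (table.chrom == chrom)
        pos = table.pos_bp[sel].astype(np.int64)
        f = table.fst[sel]
        order = np.argsort(pos, kind="stable")
        pos, f = pos[order], f[order]
        if len(pos) < 2:
            continue
        hi = np.searchsorted(pos, pos + maxd, side="right")
        counts = hi - np.arange(len(pos)) - 1
        ii = np.repeat(np.arange(len(pos)), counts)
        jj = np.concatenate(
            [np.arange(i + 1, h) for i, h in enumerate(hi) if h > i + 1]
        ) if counts.sum() else np.empty(0, dtype=np.int64)
        if len(ii) == 0:
            continue
        d = pos[jj] - pos[ii]
        keep = d > 0
        ii, jj, d = ii[keep], jj[keep], d[keep]
        b = np.minimum(d // width, n_bins - 1)
        for k in range(n_bins):
            m = b == k
            if m.any():
                bin_x[k].append(f[ii[m]])
                bin_y[k].append(f[jj[m]])

    low = np.arange(n_bins, dtype=np.int64) * width
    high = low + width
    n_pairs = np.zeros(n_bins, dtype=np.int64)
    corr = np.full(n_bins, np.nan)
    for k in range(n_bins):
        if not bin_x[k]:
            continue
        x = np.concatenate(bin_x[k])
        y = np.concatenate(bin_y[k])
        if len(x) > config.max_pairs_per_bin:
            idx = rng.choice(len(x), size=config.max_pairs_per_bin, replace=False)
            x, y = x[idx], y[idx]
        n_pairs[k] = len(x)
        if len(x) < 10:
            continue
        xs = np.concatenate([x, y])  # symmetric entry
        ys = np.concatenate([y, x])
        if xs.std() == 0.0:
            continue
        corr[k] = float(np.corrcoef(xs, ys)[0, 1])
    return DistanceCorrelation(low, high, n_pairs, corr)
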