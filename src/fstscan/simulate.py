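"""Synthetic multi-breed SNP-chip genotypes with known ground truth.

The generating model is Balding–Nichols drift: each locus has an ancestral
frequency p drawn uniformly from a configured range, and each population i
draws its own frequency from Beta(p(1-F_i)/F_i, (1-p)(1-F_i)/F_i), so the
variance of population frequency around p is F_i * p * (1-p). The nested
ANOVA Fst estimator is consistent for F under this model, which gives the
test suite a clean recovery target. Genotypes are Hardy–Weinberg binomial
draws within populations.

On top of the neutral background the generator plants:

* *selected* loci — fixed-difference (frequency 0.98 in one group of
  populations, 0.02 in the other) or redrawn with a boosted drift value —
  which the outlier scan should flag;
* *QC defects* — unmapped markers, markers with pooled MAF below 0.05 and
  markers with call rate below 90% — mutually exclusive by construction so
  the QC report counts are exactly predictable.

Loci that are supposed to survive QC are guaranteed to do so: any
non-defect locus whose realized pooled MAF falls below the planted-defect
threshold is redrawn (frequencies and genotypes). This mirrors what a SNP
chip delivers in practice — assayed markers are ascertained to be
polymorphic — and makes the post-QC marker count deterministic.

Defaults emulate the study conditions this package targets: nine pig breeds
with sample sizes 35, 22, 23, 25, 24, 40, 18, 26 and 22 (235 individuals),
strong inter-breed differentiation (drift F = 0.37), and planted defect
counts 8,383 / 8,391 / 2,709 leaving 44,652 markers after QC. The input
marker count (64,135) is chosen so that the per-step removal counts and the
post-QC total are simultaneously exact; they cannot all match a 62,123-SNP
chip, whose arithmetic is over-determined.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, Individual, MarkerRecord
from .genes import GeneInterval

#: Approximate Sus scrofa chromosome lengths (bp), autosomes 1-18 plus X.
PIG_CHROM_LAYOUT: tuple[tuple[str, int], ...] = (
    ("1", 295_000_000), ("2", 162_000_000), ("3", 144_000_000),
    ("4", 143_000_000), ("5", 111_000_000), ("6", 157_000_000),
    ("7", 134_000_000), ("8", 148_000_000), ("9", 153_000_000),
    ("10", 79_000_000), ("11", 87_000_000), ("12", 63_000_000),
    ("13", 218_000_000), ("14", 153_000_000), ("15", 157_000_000),
    ("16", 86_000_000), ("17", 69_000_000), ("18", 61_000_000),
    ("X", 144_000_000),
)

#: The nine study breeds and their sample sizes.
DEFAULT_POP_NAMES = ("TC", "BM", "LW", "WZS", "NX", "LC",
                     "Landrace", "LargeWhite", "YT")
DEFAULT_POP_SIZES = (35, 22, 23, 25, 24, 40, 18, 26, 22)


@dataclass(frozen=True)
class SimConfig:
    pop_names: tuple[str, ...] = DEFAULT_POP_NAMES
    pop_sizes: tuple[int, ...] = DEFAULT_POP_SIZES
    n_loci: int = 64_135
    drift_F: float | tuple[float, ...] = 0.37
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    n_selected: int = 100
    selected_mode: str = "fixed_difference"  # or "boosted_F"
    boosted_F: float = 0.8
    #: population names on the high-frequency side of planted loci
    group_split: tuple[str, ...] = ("Landrace", "LargeWhite")
    n_unmapped: int = 8_383
    n_low_maf: int = 8_391
    n_low_callrate: int = 2_709
    ld_block_size: int = 1
    ld_jitter_sd: float = 0.01
    background_missing_rate: float = 0.002
    #: non-defect loci are guaranteed a realized pooled MAF >= this
    maf_floor: float = 0.05
    chrom_layout: tuple[tuple[str, int], ...] = PIG_CHROM_LAYOUT
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.pop_names) != len(self.pop_sizes):
            raise ValueError("pop_names and pop_sizes lengths differ")
        planted = self.n_unmapped + self.n_low_maf + self.n_low_callrate \
            + self.n_selected
        if planted > self.n_loci:
            raise ValueError(
                f"planted loci ({planted}) exceed n_loci ({self.n_loci})"
            )
        for f in self.drift_values():
            if not 0.0 < f < 1.0:
                raise ValueError(f"drift_F must be in (0, 1), got {f}")
        if self.selected_mode not in ("fixed_difference", "boosted_F"):
            raise ValueError(f"unknown selected_mode {self.selected_mode!r}")
        unknown = set(self.group_split) - set(self.pop_names)
        if unknown:
            raise ValueError(f"group_split names not in pop_names: {sorted(unknown)}")

    def drift_values(self) -> tuple[float, ...]:
        if isinstance(self.drift_F, (int, float)):
            return (float(self.drift_F),) * len(self.pop_names)
        return tuple(float(f) for f in self.drift_F)

    @property
    def n_pops(self) -> int:
        return len(self.pop_names)

    @property
    def n_individuals(self) -> int:
        return int(sum(self.pop_sizes))


@dataclass
class SimTruth:
    """Per-locus ground truth, aligned with the emitted dataset's markers."""

    frame: pd.DataFrame  # marker_id, is_selected, defect_class, ancestral_freq, freq_<pop>...
    pop_names: tuple[str, ...]

    def defect_counts(self) -> dict[str, int]:
        counts = self.frame["defect_class"].value_counts().to_dict()
        return {k: int(counts.get(k, 0))
                for k in ("none", "unmapped", "low_maf", "low_callrate")}

    @property
    def n_selected(self) -> int:
        return int(self.frame["is_selected"].sum())

    def selected_marker_ids(self) -> set[str]:
        return set(self.frame.loc[self.frame["is_selected"], "marker_id"])

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# frequency layer


def _beta_draw(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    ratio = (1.0 - f) / f
    return rng.beta(np.maximum(p * ratio, 1e-12),
                    np.maximum((1.0 - p) * ratio, 1e-12))


def simulate_frequencies(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral and per-population frequencies, shape (L,) and (P, L).

    With ``ld_block_size > 1`` the Beta draw is made once per block and
    shared by the block's loci, with small per-locus Gaussian jitter: the
    resulting locally-shared frequencies induce correlated per-SNP Fst, the
    feature the distance-correlation diagnostic measures.
    """
    lo, hi = config.ancestral_freq_range
    bs = max(1, config.ld_block_size)
    n_blocks = math.ceil(config.n_loci / bs)
    anc_block = rng.uniform(lo, hi, n_blocks)
    drift = config.drift_values()
    pop_block = np.stack([_beta_draw(rng, anc_block, f) for f in drift])
    anc = np.repeat(anc_block, bs)[: config.n_loci]
    freqs = np.repeat(pop_block, bs, axis=1)[:, : config.n_loci]
    if bs > 1 and config.ld_jitter_sd > 0:
        freqs = freqs + rng.normal(0.0, config.ld_jitter_sd, freqs.shape)
    freqs = np.clip(freqs, 1e-3, 1.0 - 1e-3)
    return anc, freqs


def plant_outliers(
    ancestral: np.ndarray,
    freqs: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    selected_idx: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Overwrite ``n_selected`` loci with strongly divergent frequencies.

    Returns (modified frequencies, boolean is_selected flags). If
    ``selected_idx`` is not given, loci are chosen uniformly at random.
    """
    freqs = freqs.copy()
    is_selected = np.zeros(config.n_loci, dtype=bool)
    if config.n_selected == 0:
        return freqs, is_selected
    if selected_idx is None:
        selected_idx = rng.choice(config.n_loci, config.n_selected, replace=False)
    selected_idx = np.asarray(selected_idx)
    is_selected[selected_idx] = True
    high_side = np.array([name in config.group_split for name in config.pop_names])
    if config.selected_mode == "fixed_difference":
        freqs[np.ix_(high_side, selected_idx)] = 0.98
        freqs[np.ix_(~high_side, selected_idx)] = 0.02
    else:  # boosted_F: redraw with much stronger drift around the ancestral
        for g in range(config.n_pops):
            freqs[g, selected_idx] = _beta_draw(
                rng, ancestral[selected_idx], config.boosted_F
            )
    return freqs, is_selected


# ---------------------------------------------------------------------------
# genotype layer


def _pop_labels(config: SimConfig) -> np.ndarray:
    return np.repeat(np.arange(config.n_pops), config.pop_sizes)


def _draw_genotypes(
    rng: np.random.Generator, freqs: np.ndarray, config: SimConfig,
    cols: np.ndarray | None = None,
) -> np.ndarray:
    """HWE binomial dosages, shape (N, len(cols) or L)."""
    f = freqs if cols is None else freqs[:, cols]
    out = np.empty((config.n_individuals, f.shape[1]), dtype=np.int8)
    start = 0
    for g, size in enumerate(config.pop_sizes):
        out[start:start + size] = rng.binomial(2, f[g], (size, f.shape[1]))
        start += size
    return out


def _realized_maf(calls: np.ndarray) -> np.ndarray:
    present = calls != MISSING
    n = present.sum(axis=0)
    dose = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = dose / (2.0 * n)
    maf = np.minimum(f, 1.0 - f)
    maf[n == 0] = np.nan
    return maf


def simulate_genotypes(
    ancestral: np.ndarray,
    freqs: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    is_selected: np.ndarray | None = None,
    defect_idx: dict[str, np.ndarray] | None = None,
) -> tuple[GenotypeDataset, SimTruth]:
    """Sample genotypes, inject QC defects, lay markers on chromosomes.

    ``defect_idx`` maps defect class to locus indices; when omitted,
    disjoint random sets of the configured sizes are chosen. Markers that
    are not planted defects are guaranteed a realized pooled MAF >= the
    configured floor (frequencies are redrawn until they comply), so QC
    removal counts equal the planted counts exactly.
    """
    n_loci = config.n_loci
    n_ind = config.n_individuals
    if is_selected is None:
        is_selected = np.zeros(n_loci, dtype=bool)
    if defect_idx is None:
        free = np.flatnonzero(~is_selected)
        picks = rng.permutation(free)
        nu, nm, ncr = config.n_unmapped, config.n_low_maf, config.n_low_callrate
        defect_idx = {
            "unmapped": np.sort(picks[:nu]),
            "low_maf": np.sort(picks[nu:nu + nm]),
            "low_callrate": np.sort(picks[nu + nm:nu + nm + ncr]),
        }
    unmapped_idx = np.asarray(defect_idx["unmapped"], dtype=np.int64)
    low_maf_idx = np.asarray(defect_idx["low_maf"], dtype=np.int64)
    low_cr_idx = np.asarray(defect_idx["low_callrate"], dtype=np.int64)

    freqs = freqs.copy()
    # low-MAF defects: all populations near-fixed for the same rare allele
    if len(low_maf_idx):
        q = rng.uniform(0.002, 0.035, len(low_maf_idx))
        freqs[:, low_maf_idx] = q

    calls = _draw_genotypes(rng, freqs, config)

    # missingness: light background everywhere, heavy on call-rate defects
    miss_mask = rng.random((n_ind, n_loci)) < config.background_missing_rate
    for col in low_cr_idx:
        frac = rng.uniform(0.105, 0.25)
        k = math.ceil(frac * n_ind)
        rows = rng.choice(n_ind, k, replace=False)
        miss_mask[rows, col] = True
    calls[miss_mask] = MISSING

    # enforcement: non-defect loci must clear the MAF floor, low-MAF defects
    # must stay under it (realized, over non-missing calls)
    is_low_maf = np.zeros(n_loci, dtype=bool)
    is_low_maf[low_maf_idx] = True
    must_pass = ~is_low_maf
    must_pass[unmapped_idx] = False  # removed before the MAF filter anyway
    lo, hi = config.ancestral_freq_range
    for _ in range(200):
        maf = _realized_maf(calls)
        bad_hi = must_pass & ~(maf >= config.maf_floor)  # NaN counts as bad
        bad_lo = is_low_maf & ~(maf < config.maf_floor)
        if not bad_hi.any() and not bad_lo.any():
            break
        redraw_neutral = np.flatnonzero(bad_hi & ~is_selected)
        if len(redraw_neutral):
            anc_new = rng.uniform(max(lo, 0.15), min(hi, 0.85), len(redraw_neutral))
            for g, f in enumerate(config.drift_values()):
                freqs[g, redraw_neutral] = _beta_draw(rng, anc_new, f)
            freqs[:, redraw_neutral] = np.clip(freqs[:, redraw_neutral], 1e-3,
                                               1 - 1e-3)
            ancestral = ancestral.copy()
            ancestral[redraw_neutral] = anc_new
        redraw_lo = np.flatnonzero(bad_lo)
        if len(redraw_lo):
            freqs[:, redraw_lo] = rng.uniform(0.002, 0.02, len(redraw_lo))
        redraw = np.flatnonzero(bad_hi | bad_lo)
        sub = _draw_genotypes(rng, freqs, config, cols=redraw)
        sub[miss_mask[:, redraw]] = MISSING
        calls[:, redraw] = sub
    else:  # pragma: no cover - would need a pathological configuration
        raise RuntimeError("MAF enforcement did not converge")

    # marker layout: mapped loci tiled evenly over the chromosomes, in locus
    # order; unmapped loci go last (matching the dataset sort order)
    is_unmapped = np.zeros(n_loci, dtype=bool)
    is_unmapped[unmapped_idx] = True
    mapped = np.flatnonzero(~is_unmapped)
    order = np.concatenate([mapped, np.flatnonzero(is_unmapped)])

    chrom_names = [c for c, _ in config.chrom_layout]
    chrom_len = np.array([l for _, l in config.chrom_layout], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(chrom_len)])
    genome = cum[-1]
    n_mapped = len(mapped)
    gpos = ((np.arange(n_mapped) + 0.5) * genome / n_mapped).astype(np.int64)
    ci = np.searchsorted(cum, gpos, side="right") - 1
    pos = gpos - cum[ci] + 1

    markers: list[MarkerRecord] = []
    for r, locus in enumerate(mapped):
        markers.append(MarkerRecord(
            chrom=chrom_names[ci[r]],
            marker_id=f"SNP{locus:06d}",
            pos_bp=int(pos[r]),
            allele_a1="A",
            allele_a2="B",
        ))
    for locus in np.flatnonzero(is_unmapped):
        markers.append(MarkerRecord(
            chrom="0", marker_id=f"SNP{locus:06d}", pos_bp=0,
            allele_a1="A", allele_a2="B",
        ))

    individuals = []
    for name, size in zip(config.pop_names, config.pop_sizes):
        for i in range(size):
            individuals.append(Individual(f"{name}_{i + 1:03d}", name))

    dataset = GenotypeDataset(
        individuals=individuals, markers=markers, calls=calls[:, order]
    )

    defect_class = np.full(n_loci, "none", dtype=object)
    defect_class[unmapped_idx] = "unmapped"
    defect_class[low_maf_idx] = "low_maf"
    defect_class[low_cr_idx] = "low_callrate"
    truth_frame = pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in markers],
            "is_selected": is_selected[order],
            "defect_class": defect_class[order],
            "ancestral_freq": ancestral[order],
        }
    )
    for g, name in enumerate(config.pop_names):
        truth_frame[f"freq_{name}"] = freqs[g, order]
    truth = SimTruth(frame=truth_frame, pop_names=config.pop_names)
    return dataset, truth


def simulate_dataset(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """One-call generator: frequencies, planted outliers, genotypes, defects.

    Fully reproducible: all draws flow from a single generator seeded with
    ``config.seed``, in a fixed order (defect/selected locus choice,
    frequencies, planting, genotypes, missingness, enforcement redraws).
    """
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(config.n_loci)
    nu, nm, ncr = config.n_unmapped, config.n_low_maf, config.n_low_callrate
    defect_idx = {
        "unmapped": np.sort(perm[:nu]),
        "low_maf": np.sort(perm[nu:nu + nm]),
        "low_callrate": np.sort(perm[nu + nm:nu + nm + ncr]),
    }
    selected_idx = np.sort(perm[nu + nm + ncr:nu + nm + ncr + config.n_selected])
    ancestral, freqs = simulate_frequencies(config, rng)
    freqs, is_selected = plant_outliers(ancestral, freqs, config, rng, selected_idx)
    return simulate_genotypes(ancestral, freqs, config, rng, is_selected, defect_idx)


# ---------------------------------------------------------------------------
# annotation fixture


def make_annotation_fixture(
    markers: list[MarkerRecord],
    fraction: float = 0.5,
    markers_per_gene: int = 3,
) -> list[GeneInterval]:
    """Tile synthetic genes so that ~``fraction`` of mapped markers fall
    inside a gene span. Genes cover ``markers_per_gene`` consecutive markers
    each and are spread evenly along every chromosome; deterministic given
    the marker list."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    by_chrom: dict[str, list[MarkerRecord]] = {}
    for m in markers:
        if not m.is_unmapped:
            by_chrom.setdefault(m.chrom, []).append(m)
    genes: list[GeneInterval] = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: m.pos_bp)
        n = len(ms)
        span = min(markers_per_gene, n)
        n_genes = int(round(fraction * n / span)) if span else 0
        if fraction == 1.0:
            n_genes = math.ceil(n / span)
        strand = "+"
        for g in range(n_genes):
            start_m = min(int(g * n / n_genes), n - span)
            block = ms[start_m:start_m + span]
            genes.append(GeneInterval(
                gene_id=f"GENE_{chrom}_{g + 1:05d}",
                chrom=chrom,
                start_bp=max(1, block[0].pos_bp - 10),
                end_bp=block[-1].pos_bp + 10,
                strand=strand,
            ))
            strand = "-" if strand == "+" else "+"
    return genes
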