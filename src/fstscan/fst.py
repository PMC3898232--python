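"""Per-locus multi-population Fst by nested ANOVA on allele indicators.

Each diploid individual contributes two gametes carrying a 0/1 indicator for
the counted allele. A two-level nested ANOVA (populations / individuals
within populations / gametes within individuals) yields mean squares MSP,
MSI and MSG with degrees of freedom n-1, S1-n and S1, where S1 is the total
number of genotyped individuals at the locus and n the number of non-empty
populations. With the unequal-sample-size correction

    n_c = (S1 - S2/S1) / (n - 1),        S2 = sum of squared group sizes,

the estimator is

    Fst = (MSP - MSI) / (MSP + (n_c - 1) * MSI + n_c * MSG).

In terms of per-population allele frequency p_i, observed heterozygote
proportion h_i and size s_i (all computed from non-missing calls at the
locus), the sums of squares reduce to

    SSP = sum_i 2 s_i (p_i - p_bar)^2          df = n - 1
    SSI = sum_i (2 s_i p_i (1 - p_i) - s_i h_i / 2)   df = S1 - n
    SSG = sum_i s_i h_i / 2                    df = S1

with p_bar the size-weighted mean frequency. Sample sizes, n and n_c are
recomputed per locus from the non-missing calls, so missing data shrink the
design rather than bias it. Negative estimates are retained (not truncated):
truncation would distort the empirical distribution that the outlier scan
thresholds. A locus is UNDEFINED (Fst = NaN) when fewer than two populations
have data, when every population is a single individual (MSI has no degrees
of freedom), or when the denominator is zero (locus monomorphic in the
analysed sample).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

_CLAMP = 1e-12  # numerical floor: tiny negative sums of squares snap to 0


class InsufficientPopulationsError(ValueError):
    """Fewer than two populations carry data at the locus."""


class GroupingError(KeyError):
    """A breed in the data has no population assignment."""


@dataclass(frozen=True)
class Grouping:
    """Named assignment of breed labels to population indices 0..n_pops-1.

    Breeds listed in ``excluded`` take no part in the analysis (their
    individuals are dropped at every locus), supporting pairwise contrasts
    that use only a subset of breeds.
    """

    name: str
    assignment: Mapping[str, int]
    n_pops: int
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_pops < 2:
            raise ValueError("a grouping needs at least two populations")
        idx = set(self.assignment.values())
        if not idx <= set(range(self.n_pops)):
            raise ValueError("population indices must be 0..n_pops-1")

    @classmethod
    def all_populations(cls, breeds: Sequence[str], name: str = "ALLPOP") -> "Grouping":
        """Each distinct breed its own population, in sorted label order."""
        labels = sorted(set(breeds))
        return cls(name=name, assignment={b: i for i, b in enumerate(labels)},
                   n_pops=len(labels))

    def population_names(self) -> list[str]:
        names: dict[int, list[str]] = {}
        for breed, i in self.assignment.items():
            names.setdefault(i, []).append(breed)
        return ["+".join(sorted(names.get(i, []))) for i in range(self.n_pops)]

    def labels_for(self, dataset: GenotypeDataset) -> np.ndarray:
        """Population index per individual (-1 for excluded breeds); error
        names any breed that is neither assigned nor excluded."""
        out = np.empty(dataset.n_individuals, dtype=np.int64)
        for i, ind in enumerate(dataset.individuals):
            if ind.breed in self.excluded:
                out[i] = -1
            elif ind.breed not in self.assignment:
                raise GroupingError(
                    f"breed {ind.breed!r} has no population in grouping "
                    f"{self.name!r}"
                )
            else:
                out[i] = self.assignment[ind.breed]
        return out


def merge_grouping(
    breeds: Sequence[str], group_map: Mapping[str, str], name: str | None = None
) -> Grouping:
    """Pool breeds into named groups (e.g. CHN vs EURO) for pairwise Fst.

    Every breed present in ``breeds`` must appear in ``group_map``; mapping
    a breed to None (or "") excludes its individuals from the analysis.
    Group indices follow sorted group-name order, so an identity map
    reproduces the all-populations grouping.
    """
    present = sorted(set(breeds))
    for b in present:
        if b not in group_map:
            raise GroupingError(f"breed {b!r} missing from group map")
    excluded = frozenset(b for b in present if group_map[b] in (None, ""))
    kept = [b for b in present if b not in excluded]
    groups = sorted({group_map[b] for b in kept})
    gidx = {g: i for i, g in enumerate(groups)}
    assignment = {b: gidx[group_map[b]] for b in kept}
    return Grouping(
        name=name or "_VS_".join(groups),
        assignment=assignment,
        n_pops=len(groups),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# per-locus building blocks


def compute_nc(sizes: Sequence[int]) -> float:
    """Unequal-sample-size correction n_c = (S1 - S2/S1)/(n - 1).

    Computed over non-empty groups only; for n equal groups of size s this
    equals s.
    """
    sizes = [s for s in sizes if s > 0]
    n = len(sizes)
    if n < 2:
        raise InsufficientPopulationsError(
            f"n_c needs >= 2 non-empty groups, got {n}"
        )
    s1 = float(sum(sizes))
    s2 = float(sum(s * s for s in sizes))
    return (s1 - s2 / s1) / (n - 1)


@dataclass(frozen=True)
class PopLocusStats:
    """Per-population frequency/heterozygosity at one locus (non-empty pops)."""

    sizes: np.ndarray  # s_i, genotyped individuals per population
    p: np.ndarray  # counted-allele frequency per population
    h: np.ndarray  # observed heterozygote proportion per population

    @property
    def n_pops(self) -> int:
        return len(self.sizes)

    @property
    def s1(self) -> float:
        return float(self.sizes.sum())

    @property
    def p_bar(self) -> float:
        return float((self.sizes * self.p).sum() / self.sizes.sum())


def pop_locus_stats(
    dataset: GenotypeDataset, grouping: Grouping, marker_index: int
) -> PopLocusStats:
    """s_i, p_i, h_i at one marker; populations without data are dropped."""
    col = dataset.calls[:, marker_index]
    pop = grouping.labels_for(dataset)
    present = col != MISSING
    sizes, ps, hs = [], [], []
    for g in range(grouping.n_pops):
        sel = present & (pop == g)
        s = int(sel.sum())
        if s == 0:
            continue
        d = col[sel]
        sizes.append(s)
        ps.append(float(d.sum()) / (2 * s))
        hs.append(float((d == 1).sum()) / s)
    if len(sizes) < 2:
        raise InsufficientPopulationsError(
            f"marker {dataset.markers[marker_index].marker_id}: "
            f"data in {len(sizes)} population(s)"
        )
    return PopLocusStats(
        sizes=np.array(sizes, dtype=float),
        p=np.array(ps, dtype=float),
        h=np.array(hs, dtype=float),
    )


def anova_mean_squares(stats: PopLocusStats) -> tuple[float, float, float]:
    """(MSP, MSI, MSG) from per-population locus statistics.

    Raises ValueError when MSI has no degrees of freedom (every population a
    single individual); scan code maps that to an UNDEFINED record.
    """
    s, p, h = stats.sizes, stats.p, stats.h
    n = stats.n_pops
    s1 = stats.s1
    pbar = stats.p_bar
    ssp = float((2.0 * s * (p - pbar) ** 2).sum())
    ssi = float((2.0 * s * p * (1.0 - p) - s * h / 2.0).sum())
    ssg = float((s * h / 2.0).sum())
    if -_CLAMP < ssi < 0.0:
        ssi = 0.0
    if s1 - n <= 0:
        raise ValueError("MSI undefined: every population is a single individual")
    return ssp / (n - 1), ssi / (s1 - n), ssg / s1


@dataclass(frozen=True)
class FstRecord:
    """ANOVA components and the Fst estimate at one marker.

    ``fst`` is NaN when the locus is UNDEFINED (monomorphic in the analysed
    sample, <2 populations with data, or no within-population degrees of
    freedom).
    """

    marker_id: str
    msp: float
    msi: float
    msg: float
    n_c: float
    fst: float
    n_pops_used: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.fst)


def fst_locus(
    dataset: GenotypeDataset, grouping: Grouping, marker_index: int
) -> FstRecord:
    """Fst at a single marker; degeneracy is encoded in the record, not raised."""
    marker_id = dataset.markers[marker_index].marker_id
    try:
        stats = pop_locus_stats(dataset, grouping, marker_index)
    except InsufficientPopulationsError:
        return FstRecord(marker_id, math.nan, math.nan, math.nan, math.nan,
                         math.nan, 0)
    n_c = compute_nc(stats.sizes)
    try:
        msp, msi, msg = anova_mean_squares(stats)
    except ValueError:
        return FstRecord(marker_id, math.nan, math.nan, math.nan, n_c,
                         math.nan, stats.n_pops)
    denom = msp + (n_c - 1.0) * msi + n_c * msg
    fst = (msp - msi) / denom if denom != 0.0 else math.nan
    return FstRecord(marker_id, msp, msi, msg, n_c, fst, stats.n_pops)


# ---------------------------------------------------------------------------
# genome-wide scan


@dataclass
class FstTable:
    """Per-marker Fst records for one grouping, in the dataset's map order."""

    grouping_name: str
    marker_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    msp: np.ndarray
    msi: np.ndarray
    msg: np.ndarray
    n_c: np.ndarray
    fst: np.ndarray
    n_pops_used: np.ndarray

    def __len__(self) -> int:
        return len(self.marker_ids)

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.fst)

    @property
    def defined_fst(self) -> np.ndarray:
        return self.fst[self.defined_mask]

    @property
    def mean_fst(self) -> float:
        """Arithmetic mean of defined per-locus estimates."""
        return float(self.defined_fst.mean())

    @property
    def sd_fst(self) -> float:
        return float(self.defined_fst.std(ddof=1))

    def ratio_of_sums_fst(self) -> float:
        """Multilocus estimate: summed numerators over summed denominators.

        Reported for reference; outlier thresholds use the per-locus values.
        """
        d = self.defined_mask
        num = (self.msp[d] - self.msi[d]).sum()
        den = (self.msp[d] + (self.n_c[d] - 1) * self.msi[d]
               + self.n_c[d] * self.msg[d]).sum()
        return float(num / den)

    def records(self) -> Iterator[FstRecord]:
        for i in range(len(self)):
            yield FstRecord(
                self.marker_ids[i], float(self.msp[i]), float(self.msi[i]),
                float(self.msg[i]), float(self.n_c[i]), float(self.fst[i]),
                int(self.n_pops_used[i]),
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "n_pops_used": self.n_pops_used,
                "MSP": self.msp,
                "MSI": self.msi,
                "MSG": self.msg,
                "n_c": self.n_c,
                "fst": self.fst,
            }
        )

    def write_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def fst_scan(dataset: GenotypeDataset, grouping: Grouping) -> FstTable:
    """Vectorised per-marker Fst over the whole dataset for one grouping."""
    calls = dataset.calls
    n_ind, n_loci = calls.shape
    pop = grouping.labels_for(dataset)
    g_total = grouping.n_pops

    s = np.zeros((g_total, n_loci))
    dose = np.zeros((g_total, n_loci))
    het = np.zeros((g_total, n_loci))
    for g in range(g_total):
        sub = calls[pop == g]
        present = sub != MISSING
        s[g] = present.sum(axis=0)
        dose[g] = np.where(present, sub, 0).sum(axis=0)
        het[g] = (sub == 1).sum(axis=0)

    nonempty = s > 0
    n = nonempty.sum(axis=0).astype(float)
    s1 = s.sum(axis=0)
    s2 = (s**2).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nonempty, dose / (2.0 * np.maximum(s, 1)), 0.0)
        h = np.where(nonempty, het / np.maximum(s, 1), 0.0)
        pbar = dose.sum(axis=0) / (2.0 * s1)

        ssp = (2.0 * s * (p - pbar) ** 2 * nonempty).sum(axis=0)
        ssi = ((2.0 * s * p * (1.0 - p) - s * h / 2.0) * nonempty).sum(axis=0)
        ssg = (s * h / 2.0).sum(axis=0)
        ssi = np.where((ssi < 0) & (ssi > -_CLAMP), 0.0, ssi)

        computable = (n >= 2) & (s1 - n > 0)
        msp = np.where(computable, ssp / np.maximum(n - 1.0, 1), np.nan)
        msi = np.where(computable, ssi / np.maximum(s1 - n, 1), np.nan)
        msg = np.where(computable & (s1 > 0), ssg / np.maximum(s1, 1), np.nan)
        n_c = np.where(n >= 2, (s1 - s2 / np.maximum(s1, 1)) / np.maximum(n - 1.0, 1),
                       np.nan)
        denom = msp + (n_c - 1.0) * msi + n_c * msg
        fst = np.where(computable & (denom != 0.0), (msp - msi) / denom, np.nan)

    markers = dataset.marker_frame()
    return FstTable(
        grouping_name=grouping.name,
        marker_ids=markers["marker_id"].to_numpy(),
        chrom=markers["chrom"].to_numpy(),
        pos_bp=markers["pos_bp"].to_numpy(dtype=np.int64),
        msp=msp,
        msi=msi,
        msg=msg,
        n_c=n_c,
        fst=fst,
        n_pops_used=n.astype(np.int64),
    )
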