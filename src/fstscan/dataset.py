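"""In-memory representation of a diploid biallelic SNP genotype panel.

Genotypes are stored as an individuals x markers matrix of allele dosages
(number of copies of ``allele_a2``), with ``MISSING`` (-1) for no-calls.
Markers carry chromosome / base-pair coordinates (1-based); a marker with
chromosome "0" (or empty) or position 0 is *unmapped*. Individuals carry a
breed label, which downstream code uses as the population label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Sentinel dosage value for a missing genotype call.
MISSING: int = -1


@dataclass(frozen=True)
class MarkerRecord:
    """A single SNP: coordinates plus the two allele codes.

    ``pos_bp`` is 1-based; ``pos_bp == 0`` or chromosome "0"/empty marks the
    marker as unmapped. ``allele_a2`` is the counted allele (dosage 2 =
    homozygous a2); by the reader's convention it is the lexicographically
    larger observed allele.
    """

    chrom: str
    marker_id: str
    pos_bp: int
    allele_a1: str = "0"
    allele_a2: str = "0"

    @property
    def is_unmapped(self) -> bool:
        return self.chrom in ("0", "") or self.pos_bp == 0

    def __post_init__(self) -> None:
        if self.pos_bp < 0:
            raise ValueError(
                f"marker {self.marker_id}: pos_bp must be >= 0, got {self.pos_bp}"
            )


@dataclass(frozen=True)
class Individual:
    individual_id: str
    breed: str


def _chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Numeric chromosomes first in numeric order, then others lexicographic."""
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


@dataclass
class GenotypeDataset:
    """Individuals x markers dosage matrix with breed labels and a marker map.

    Invariants enforced on construction: matrix shape matches the two lists,
    every call is in {-1, 0, 1, 2}, individual ids are unique. Markers are
    expected in (chrom, pos) sorted order with unmapped markers last; use
    :meth:`sorted_by_position` after ad-hoc construction.
    """

    individuals: list[Individual]
    markers: list[MarkerRecord]
    calls: np.ndarray  # int8, shape (n_individuals, n_markers)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.individuals), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.markers)} markers"
            )
        if self.calls.size:
            bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"invalid dosage {self.calls[i, j]} at individual {i}, marker {j}"
                )
        ids = [ind.individual_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids in dataset")

    # -- basic views -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def breeds(self) -> np.ndarray:
        return np.array([ind.breed for ind in self.individuals], dtype=object)

    def marker_ids(self) -> np.ndarray:
        return np.array([m.marker_id for m in self.markers], dtype=object)

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [m.chrom for m in self.markers],
                "marker_id": [m.marker_id for m in self.markers],
                "pos_bp": [m.pos_bp for m in self.markers],
                "allele_a1": [m.allele_a1 for m in self.markers],
                "allele_a2": [m.allele_a2 for m in self.markers],
            }
        )

    # -- transforms --------------------------------------------------------

    def sorted_by_position(self) -> "GenotypeDataset":
        """Markers sorted by (chrom, pos_bp); unmapped markers sort last."""
        order = sorted(
            range(self.n_markers),
            key=lambda j: (
                self.markers[j].is_unmapped,
                _chrom_sort_key(self.markers[j].chrom),
                self.markers[j].pos_bp,
                j,
            ),
        )
        return GenotypeDataset(
            individuals=list(self.individuals),
            markers=[self.markers[j] for j in order],
            calls=self.calls[:, order],
        )

    def subset_markers(self, keep: np.ndarray) -> "GenotypeDataset":
        """New dataset restricted to marker indices/boolean mask ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeDataset(
            individuals=list(self.individuals),
            markers=[self.markers[j] for j in keep],
            calls=self.calls[:, keep],
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.individuals == other.individuals
            and self.markers == other.markers
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class DatasetSummary:
    n_individuals: int
    n_markers: int
    breed_counts: dict[str, int]
    chromosome_marker_counts: dict[str, int]
    missing_fraction: float

    def __str__(self) -> str:  # pragma: no cover - formatting only
        lines = [
            f"individuals: {self.n_individuals}",
            f"markers:     {self.n_markers}",
            f"missing:     {self.missing_fraction:.4f}",
            "breeds:      "
            + ", ".join(f"{b}={n}" for b, n in self.breed_counts.items()),
            "chromosomes: "
            + ", ".join(f"{c}={n}" for c, n in self.chromosome_marker_counts.items()),
        ]
        return "\n".join(lines)


def summarize_dataset(dataset: GenotypeDataset) -> DatasetSummary:
    """Headline counts: individuals, markers, per-breed and per-chromosome
    tallies, and the overall missing-call fraction."""
    breed_counts: dict[str, int] = {}
    for ind in dataset.individuals:
        breed_counts[ind.breed] = breed_counts.get(ind.breed, 0) + 1
    chrom_counts: dict[str, int] = {}
    for m in dataset.markers:
        chrom_counts[m.chrom] = chrom_counts.get(m.chrom, 0) + 1
    total = dataset.calls.size
    missing = float((dataset.calls == MISSING).sum()) / total if total else 0.0
    return DatasetSummary(
        n_individuals=dataset.n_individuals,
        n_markers=dataset.n_markers,
        breed_counts=breed_counts,
        chromosome_marker_counts=chrom_counts,
        missing_fraction=missing,
    )
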