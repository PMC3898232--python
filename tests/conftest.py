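from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fstscan.dataset import MISSING, GenotypeDataset, Individual, MarkerRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def dataset_from_pop_dosages(
    pop_dosages: list[list[int]], n_markers: int = 1
) -> GenotypeDataset:
    """Single-marker (or replicated-marker) dataset from per-population
    dosage lists; -1 marks a missing call."""
    individuals = []
    rows = []
    for g, dosages in enumerate(pop_dosages):
        for j, d in enumerate(dosages):
            individuals.append(Individual(f"P{g}_{j}", f"P{g}"))
            rows.append([d] * n_markers)
    markers = [
        MarkerRecord("1", f"m{k}", 1000 * (k + 1), "A", "B")
        for k in range(n_markers)
    ]
    return GenotypeDataset(individuals, markers, np.array(rows, dtype=np.int8))


def random_small_dataset(rng: np.random.Generator) -> GenotypeDataset:
    """2-6 populations, 2-30 individuals each, random allele frequencies and
    random missingness: the fuzz corpus for estimator-oracle equivalence."""
    n_pops = int(rng.integers(2, 7))
    n_markers = int(rng.integers(1, 4))
    individuals, rows = [], []
    for g in range(n_pops):
        size = int(rng.integers(2, 31))
        p = rng.uniform(0.0, 1.0, n_markers)
        for j in range(size):
            dos = rng.binomial(2, p)
            miss = rng.random(n_markers) < 0.15
            dos = np.where(miss, MISSING, dos)
            individuals.append(Individual(f"P{g}_{j}", f"P{g}"))
            rows.append(dos)
    markers = [
        MarkerRecord("1", f"m{k}", 1000 * (k + 1), "A", "B")
        for k in range(n_markers)
    ]
    return GenotypeDataset(individuals, markers,
                           np.array(rows, dtype=np.int8))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140115)
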