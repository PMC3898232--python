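"""Population-structure PCA on the standardized genotype matrix.

Missing calls are imputed to the per-marker mean dosage; each marker column
is centred by 2*p_hat and scaled by sqrt(2*p_hat*(1-p_hat)), the expected
binomial (drift) standard deviation — the population-genetics standard
scaling that makes eigenstructure interpretable under genetic drift.
Monomorphic and fully-missing markers carry no structure information and
are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset


def standardize_genotypes(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Return (standardized matrix, indices of retained markers)."""
    calls = dataset.calls.astype(float)
    present = dataset.calls != MISSING
    n_called = present.sum(axis=0)
    fully_missing = n_called == 0
    if fully_missing.any():
        warnings.warn(
            f"dropping {int(fully_missing.sum())} fully-missing marker(s) from PCA"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_dose = np.where(present, calls, 0.0).sum(axis=0) / np.maximum(n_called, 1)
    p_hat = mean_dose / 2.0
    poly = ~fully_missing & (p_hat > 0.0) & (p_hat < 1.0)
    keep = np.flatnonzero(poly)
    if len(keep) == 0:
        raise ValueError("no polymorphic markers available for PCA")
    x = np.where(present[:, keep], calls[:, keep], mean_dose[keep])
    x -= mean_dose[keep]
    x /= np.sqrt(2.0 * p_hat[keep] * (1.0 - p_hat[keep]))
    return x, keep


@dataclass
class PCAResult:
    """Scores, per-component variance fractions and loadings."""

    coordinates: np.ndarray  # (n_individuals, k)
    variance_fraction: np.ndarray  # (k,), of the total variance over all ranks
    components: np.ndarray  # (k, n_markers) loading vectors
    k: int

    def to_frame(self, dataset: GenotypeDataset) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "individual_id": [i.individual_id for i in dataset.individuals],
                "breed": [i.breed for i in dataset.individuals],
            }
        )
        for j in range(self.k):
            df[f"PC{j + 1}"] = self.coordinates[:, j]
        return df


def run_pca(matrix: np.ndarray, k: int) -> PCAResult:
    """Top-k principal components of a standardized matrix by SVD.

    Scores are projections onto the right singular directions; variance
    fractions are eigenvalue shares of the total over all ranks. If k
    exceeds the numerical rank it is truncated with a warning. Sign is made
    deterministic: each loading vector sums to a non-negative value.
    """
    matrix = np.asarray(matrix, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    tol = s.max(initial=0.0) * max(matrix.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if k > rank:
        warnings.warn(f"k={k} exceeds matrix rank {rank}; truncating")
        k = rank
    if k == 0:
        raise ValueError("matrix has rank 0; no components to extract")
    lam = s**2
    var_frac = lam[:k] / lam.sum()
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].copy()
    flip = loadings.sum(axis=1) < 0
    loadings[flip] *= -1.0
    scores[:, flip] *= -1.0
    return PCAResult(
        coordinates=scores,
        variance_fraction=var_frac,
        components=loadings,
        k=k,
    )


def pca_dataset(dataset: GenotypeDataset, k: int = 10) -> PCAResult:
    """Convenience wrapper: standardize then run PCA on a dataset."""
    x, _ = standardize_genotypes(dataset)
    return run_pca(x, min(k, min(x.shape)))
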