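"""Population structure: PCA on dosages, PC-set selection, centered kinship, Gower similarity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from idcgwas.genio import GenotypeMatrix


def _dosage_no_missing(g: GenotypeMatrix) -> np.ndarray:
    d = g.dosage
    if np.isnan(d).any():
        raise ValueError("dosage matrix contains missing values; impute first")
    return d


@dataclass
class StructureModel:
    """PCA of the column-centered dosage matrix (covariance form, no unit scaling)."""

    scores: np.ndarray                 # (n, k) sample scores, k = min(n-1, m)
    explained_variance_ratio: np.ndarray

    def to_frame(self, samples) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame({"sample": samples, **cols})


def pca(g: GenotypeMatrix) -> StructureModel:
    """Principal components of the column-centered dosage matrix via SVD.

    Variance fractions are eigenvalues of the covariance matrix over total
    variance; they sum to 1 over the min(n-1, m) retained components.
    """
    d = _dosage_no_missing(g)
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    xc = d - d.mean(axis=0)
    if not np.any(xc):
        raise ValueError("all markers constant: zero total genotypic variance")
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    k = min(n - 1, d.shape[1])
    u, s = u[:, :k], s[:k]
    return StructureModel(scores=u * s, explained_variance_ratio=s**2 / np.sum(s**2))


def select_pcs(s: StructureModel, threshold: float) -> int:
    """Smallest k whose cumulative explained-variance fraction reaches ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    cum = np.cumsum(s.explained_variance_ratio)
    reached = np.flatnonzero(cum >= threshold - 1e-12)
    if reached.size == 0:
        raise ValueError(
            f"cumulative variance {cum[-1]:.4f} never reaches threshold {threshold}"
        )
    return int(reached[0]) + 1


def kinship_centered(g: GenotypeMatrix) -> np.ndarray:
    """Centered relatedness matrix K = Xc Xc^T / m over m markers.

    Columns of the dosage matrix are mean-centered; rows of K sum to zero and
    K is positive semi-definite by construction.
    """
    d = _dosage_no_missing(g)
    m = d.shape[1]
    if m < 2:
        raise ValueError("kinship needs at least 2 markers")
    xc = d - d.mean(axis=0)
    if not np.any(xc):
        raise ValueError("all markers monomorphic: kinship undefined")
    return (xc @ xc.T) / m


def gower_similarity(g: GenotypeMatrix) -> np.ndarray:
    """Gower similarity on interval-scaled dosages with fixed range 2.

    s(i, j) = mean over markers of 1 - |d_i - d_j| / 2, so identical samples
    score 1 and fully opposite homozygotes score 0, independent of the panel's
    observed dosage range.
    """
    d = _dosage_no_missing(g)
    m = d.shape[1]
    dist = squareform(pdist(d, metric="cityblock")) / (2.0 * m)
    return 1.0 - dist


def matrix_frame(mat: np.ndarray, samples) -> pd.DataFrame:
    """Square matrix as a DataFrame with sample ids on both axes."""
    return pd.DataFrame(mat, index=list(samples), columns=list(samples))
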