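"""Principal-component dimension reduction of voxel features.

SVD-based PCA with mean centering; the number of retained components
follows the Kaiser rule (covariance eigenvalues > 1) by default, with a
mean-eigenvalue alternative because the literal rule is scale-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA


@dataclass(frozen=True)
class PCAModel:
    """Orthonormal loadings and spectrum of a fitted PCA.

    ``loadings`` has one column per retained component; ``eigenvalues``
    holds the full descending covariance spectrum ``s_j^2 / (n - 1)``.
    """

    mean_vector: np.ndarray
    loadings: np.ndarray  # (p, k), orthonormal columns
    eigenvalues: np.ndarray  # full spectrum, descending
    k: int
    explained_variance_fraction: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean_vector.size:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model {self.mean_vector.size}"
            )
        return (X - self.mean_vector) @ self.loadings


def fit_pca(X: np.ndarray, criterion: str = "kaiser") -> PCAModel:
    """Fit PCA and retain components by the given eigenvalue criterion.

    ``criterion`` is ``"kaiser"`` (eigenvalue > 1) or ``"mean-eigenvalue"``
    (eigenvalue above the mean eigenvalue). At least one component is
    always retained.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 rows")
    if np.allclose(X, X[0]):
        raise ValueError("feature matrix is constant; mask or rendering is degenerate")
    n = X.shape[0]
    sk = _SkPCA(n_components=min(n - 1, X.shape[1]), svd_solver="full")
    sk.fit(X)
    eigenvalues = sk.explained_variance_  # s^2 / (n - 1), descending
    if criterion == "kaiser":
        k = int(np.sum(eigenvalues > 1.0))
    elif criterion == "mean-eigenvalue":
        k = int(np.sum(eigenvalues > eigenvalues.mean()))
    else:
        raise ValueError(f"unknown retention criterion {criterion!r}")
    k = max(k, 1)
    total = float(eigenvalues.sum())
    frac = float(eigenvalues[:k].sum() / total) if total > 0 else 1.0
    return PCAModel(
        mean_vector=sk.mean_.copy(),
        loadings=sk.components_[:k].T.copy(),
        eigenvalues=eigenvalues.copy(),
        k=k,
        explained_variance_fraction=frac,
    )
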