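"""Relevance vector regression with a linear kernel.

Sparse Bayesian regression in the style of Tipping's relevance vector
machine. Each training scan contributes one kernel basis function (plus an
explicit bias column); independent Gamma-type hyperpriors give every basis
its own precision ``alpha_i``, and type-II maximum likelihood drives most
precisions to infinity, pruning their bases. The surviving training scans
are the "relevance vectors". No cross-validated hyperparameter search is
required, which is the property that makes the method attractive for
small neuroimaging samples.

Update equations (iterated to a fixed point):

    Sigma = (A + beta Phi^T Phi)^{-1}        A = diag(alpha)
    m     = beta Sigma Phi^T y
    gamma_i = 1 - alpha_i Sigma_ii
    alpha_i <- gamma_i / m_i^2
    beta    <- (N - sum_i gamma_i) / ||y - Phi m||^2
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

#: Bases with alpha above this are pruned from the model.
DEFAULT_PRUNE_THRESHOLD = 1e9
DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 1000
#: Noise precision is capped here so exactly-realizable targets stay finite.
BETA_CAP = 1e12


@dataclass(frozen=True)
class RVRModel:
    """Fitted sparse kernel regressor.

    ``active`` indexes the retained columns of the full basis
    ``Phi = [1, K]`` (0 is the bias column; ``i >= 1`` is training scan
    ``i - 1``). ``relevance_indices`` are the retained training-scan rows.
    """

    weights: np.ndarray
    alphas: np.ndarray
    beta: float
    active: np.ndarray
    training_scores: np.ndarray
    converged: bool
    n_iter: int
    log_marginal: float

    @property
    def bias(self) -> float:
        """Weight of the constant basis (0.0 when it was pruned)."""
        hit = np.where(self.active == 0)[0]
        return float(self.weights[hit[0]]) if hit.size else 0.0

    @property
    def relevance_indices(self) -> np.ndarray:
        return self.active[self.active > 0] - 1

    def predict(self, scores: np.ndarray) -> np.ndarray:
        """Predict targets for rows of PCA scores."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[1] != self.training_scores.shape[1]:
            raise ValueError(
                f"score dimension {scores.shape[1]} does not match "
                f"training dimension {self.training_scores.shape[1]}"
            )
        phi = _design(scores @ self.training_scores.T)[:, self.active]
        return phi @ self.weights


def _design(K: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(K.shape[0]), K])


def linear_kernel(scores: np.ndarray, other: np.ndarray | None = None) -> np.ndarray:
    other = scores if other is None else other
    return np.asarray(scores, float) @ np.asarray(other, float).T


def _posterior(phi: np.ndarray, y: np.ndarray, alpha: np.ndarray, beta: float, it: int):
    A = np.diag(alpha)
    H = A + beta * phi.T @ phi
    try:
        chol = cho_factor(H, lower=True)
    except LinAlgError as err:
        raise RuntimeError(f"singular posterior solve at iteration {it}") from err
    sigma = cho_solve(chol, np.eye(H.shape[0]))
    m = beta * (sigma @ (phi.T @ y))
    return m, sigma


def log_marginal_likelihood(
    scores: np.ndarray, y: np.ndarray, alphas: np.ndarray, beta: float
) -> float:
    """Type-II log likelihood log p(y | alpha, beta) for the linear-kernel basis.

    ``alphas`` has one entry per basis (bias first); entries that are
    infinite (or above the pruning threshold) are treated as removed.
    """
    y = np.asarray(y, float)
    phi = _design(linear_kernel(scores))
    keep = np.isfinite(alphas) & (alphas < DEFAULT_PRUNE_THRESHOLD)
    phi = phi[:, keep]
    C = np.eye(len(y)) / beta + (phi / alphas[keep]) @ phi.T
    chol = cho_factor(C, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
    quad = float(y @ cho_solve(chol, y))
    n = len(y)
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def fit_rvr(
    scores: np.ndarray,
    y: np.ndarray,
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    fixed_alpha: float | None = None,
    fixed_beta: float | None = None,
) -> RVRModel:
    """Fit the relevance vector regressor on PCA scores and ages.

    With ``fixed_alpha`` and ``fixed_beta`` both given, the posterior mean
    is computed once with those hyperparameters held fixed (the
    ridge-regression limit) and no pruning occurs.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if scores.ndim != 2 or scores.shape[0] != n:
        raise ValueError("scores must be (n_scans, k) matching len(y)")
    if n < 3:
        raise ValueError(f"need at least 3 training scans, got {n}")

    phi_full = _design(linear_kernel(scores))
    m_bases = phi_full.shape[1]

    if fixed_alpha is not None and fixed_beta is not None:
        alphas = np.full(m_bases, float(fixed_alpha))
        beta = float(fixed_beta)
        m, _ = _posterior(phi_full, y, alphas, beta, it=0)
        lml = log_marginal_likelihood(scores, y, alphas, beta)
        return RVRModel(m, alphas, beta, np.arange(m_bases), scores.copy(), True, 0, lml)

    alphas = np.full(m_bases, 1.0 / n**2)
    var_y = float(np.var(y))
    beta = 10.0 / var_y if var_y > 0 else 1.0
    active = np.arange(m_bases)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        phi = phi_full[:, active]
        a = alphas[active]
        m, sigma = _posterior(phi, y, a, beta, it)
        gamma = 1.0 - a * np.diag(sigma)
        with np.errstate(divide="ignore"):
            new_a = gamma / np.square(m)
        new_a = np.where(np.isfinite(new_a) & (new_a > 0), new_a, np.inf)
        resid = y - phi @ m
        rss = float(resid @ resid)
        denom = max(rss, n / BETA_CAP)
        beta = max(float(n - np.sum(gamma)), 1e-12) / denom

        prev = alphas[active]
        keep = new_a < prune_threshold
        delta = np.abs(np.log(new_a[keep]) - np.log(prev[keep])) if keep.any() else np.array([0.0])
        alphas[active] = new_a
        active = active[keep]
        if active.size == 0:
            raise RuntimeError(f"all bases pruned at iteration {it}; target may be degenerate")
        if delta.max() < tol:
            converged = True
            break

    phi = phi_full[:, active]
    m, _ = _posterior(phi, y, alphas[active], beta, it)
    lml = log_marginal_likelihood(scores, y, alphas, beta)
    return RVRModel(m, alphas[active], beta, active, scores.copy(), converged, it, lml)
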