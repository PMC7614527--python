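"""Compositional PCA of state fractional occupancies.

Fractional occupancies live on the K-simplex (they sum to one), so ordinary
PCA is inappropriate.  The alpha-transformation maps compositions to K-1
unconstrained coordinates via a power transform followed by orthonormal
Helmert contrasts; at alpha = 1 this is the linear map z = H (K x - 1).
PCA is run on the transformed coordinates, the number of components is
chosen by MacArthur's broken-stick criterion, and the retained loadings are
varimax-rotated.  Loadings are mapped back to state space (H^T L) purely for
interpretation; scores are always computed in transform space.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import helmert
from statsmodels.multivariate.factor_rotation import rotate_factors

__all__ = [
    "CompositionModel",
    "alpha_transform",
    "fit_pca",
    "broken_stick",
    "broken_stick_select",
    "varimax_rotate",
    "varimax_criterion",
    "fit_composition_pca",
    "component_scores",
]

_SIMPLEX_ATOL = 1e-8


def _check_simplex(F: np.ndarray) -> np.ndarray:
    F = np.atleast_2d(np.asarray(F, dtype=float))
    if np.any(F < -_SIMPLEX_ATOL):
        raise ValueError("composition has negative entries")
    if not np.allclose(F.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("composition rows must sum to 1")
    return F


def alpha_transform(F: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Map N compositions on the K-simplex to N x (K-1) coordinates.

    z = H ((K u^alpha / sum(u^alpha) - 1) / alpha) per row, with H the
    (K-1) x K orthonormal Helmert sub-matrix.  For alpha = 1 this reduces to
    z = H (K x - 1).  The uniform composition maps to the zero vector for any
    alpha.  alpha = 0 (the isometric log-ratio limit) is not supported.
    """
    if alpha == 0:
        raise ValueError("alpha = 0 (log-ratio limit) is not supported")
    F = _check_simplex(F)
    K = F.shape[1]
    if alpha <= 0 and np.any(F <= 0):
        raise ValueError("zero composition entries require alpha > 0")
    H = helmert(K)
    P = F**alpha
    # K*u - 1 == K*(u - mean(u)) with u = P/sum(P); centering P before the
    # division makes the uniform composition cancel exactly
    Z = (K / alpha) * (P - P.mean(axis=1, keepdims=True)) / P.sum(axis=1, keepdims=True)
    return Z @ H.T


def fit_pca(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """PCA via eigen-decomposition of the column-centered covariance.

    Returns (eigenvalues desc, loadings with orthonormal columns, scores,
    column means).  Loadings signs are fixed so the largest-magnitude entry of
    each column is positive, making the decomposition deterministic.
    """
    Z = np.asarray(coords, dtype=float)
    n, p = Z.shape
    if n <= p:
        import warnings

        warnings.warn(f"PCA with n={n} <= dimensions={p}: rank-deficient covariance", stacklevel=2)
    mean = Z.mean(axis=0)
    Zc = Z - mean
    cov = (Zc.T @ Zc) / (n - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    scores = Zc @ V
    return w, V, scores, mean


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick expectations b_k = (1/p) * sum_{i=k}^{p} 1/i."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def broken_stick_select(eigenvalues: np.ndarray) -> tuple[int, bool]:
    """Number of leading components whose variance share beats the broken stick.

    Returns (n_selected, forced).  A component is retained while its
    eigenvalue proportion strictly exceeds the broken-stick expectation; the
    count is the length of the leading run.  An empty run is forced to 1
    (flagged) because downstream models need at least one score.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be non-increasing")
    total = lam.sum()
    if total <= 0:
        raise ValueError("eigenvalue sum must be positive")
    if len(lam) == 1:
        return 1, False
    props = lam / total
    b = broken_stick(len(lam))
    n = 0
    for pk, bk in zip(props, b):
        if pk > bk:
            n += 1
        else:
            break
    if n == 0:
        return 1, True
    return n, False


def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax objective: sum over columns of the variance of squared loadings."""
    L2 = np.asarray(L, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


def varimax_rotate(loadings: np.ndarray, n_selected: int) -> tuple[np.ndarray, np.ndarray]:
    """Varimax-rotate the first ``n_selected`` loading columns.

    Kaiser row normalization is not applied (a single retained component is
    unaffected either way).  For one component the rotation is the 1x1
    identity.
    Returns (rotated loadings, orthogonal rotation matrix R).
    """
    L = np.asarray(loadings, dtype=float)[:, :n_selected]
    if n_selected < 1:
        raise ValueError("n_selected must be >= 1")
    if n_selected == 1:
        return L.copy(), np.eye(1)
    rotated, R = rotate_factors(L, "varimax")
    return rotated, R


@dataclass(frozen=True)
class CompositionModel:
    """Fitted compositional-PCA model for fractional-occupancy simplices."""

    alpha: float
    helmert_basis: np.ndarray  # (K-1, K)
    eigenvalues: np.ndarray  # (K-1,) non-increasing
    raw_loadings: np.ndarray  # (K-1, K-1)
    n_selected: int
    selection_forced: bool
    rotation: np.ndarray  # (n_selected, n_selected) orthogonal
    rotated_loadings: np.ndarray  # (K-1, n_selected)
    training_mean: np.ndarray  # (K-1,) transform-space mean

    @property
    def n_states(self) -> int:
        return self.helmert_basis.shape[1]

    @property
    def variance_explained(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def state_space_loadings(self) -> np.ndarray:
        """K x n_selected loadings mapped back to state space (display only)."""
        return self.helmert_basis.T @ self.rotated_loadings


def fit_composition_pca(FO: np.ndarray, alpha: float = 1.0) -> CompositionModel:
    """alpha-transform -> PCA -> broken-stick selection -> varimax."""
    F = _check_simplex(FO)
    Z = alpha_transform(F, alpha)
    lam, V, _, mean = fit_pca(Z)
    n_sel, forced = broken_stick_select(lam)
    rotated, R = varimax_rotate(V, n_sel)
    return CompositionModel(
        alpha=float(alpha),
        helmert_basis=helmert(F.shape[1]),
        eigenvalues=lam,
        raw_loadings=V,
        n_selected=n_sel,
        selection_forced=forced,
        rotation=R,
        rotated_loadings=rotated,
        training_mean=mean,
    )


def component_scores(FO: np.ndarray, model: CompositionModel) -> np.ndarray:
    """Project compositions onto the fitted rotated components.

    scores = (alpha_transform(FO) - training mean) @ rotated_loadings.  New
    compositions must lie on the same K-simplex as the training data.
    """
    F = _check_simplex(FO)
    if F.shape[1] != model.n_states:
        raise ValueError("composition has wrong number of states for this model")
    Z = alpha_transform(F, model.alpha)
    return (Z - model.training_mean) @ model.rotated_loadings
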