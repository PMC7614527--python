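"""Shared-covariance multivariate Gaussian hidden Markov models.

The model has K hidden brain states evolving as a first-order Markov chain
(initial distribution ``pi``, row-stochastic transition matrix ``A``).  The
observation at each fMRI volume is a C-vector of ICA-component amplitudes,
emitted from a multivariate normal whose mean ``mu_k`` depends on the active
state while a single covariance ``Sigma`` is shared by all states — states
differ in mean activation only, not in covariance structure.

Fitting is maximum-likelihood EM (Baum-Welch) on temporally concatenated,
per-scan standardized time courses.  The forward-backward recursions restart
at every scan boundary, so no transition is ever counted across subjects.
State posteriors (``gamma``, soft state assignments per volume, and ``xi``,
expected transition counts) are the substrate for all downstream temporal
metrics; no hard Viterbi decoding is used by default.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "HMMModel",
    "StatePosterior",
    "standardize_timecourse",
    "concatenate_scans",
    "forward_backward",
    "fit_hmm",
    "match_states",
]


@dataclass(frozen=True)
class HMMModel:
    """A fitted (or ground-truth) K-state Gaussian HMM with shared covariance.

    Parameters are stored as plain arrays: ``initial_probs`` (K,),
    ``transition_matrix`` (K, K) row-stochastic, ``state_means`` (K, C) in
    z-units of the standardized time courses, and ``covariance`` (C, C)
    symmetric positive definite.  Fit diagnostics are attached when the model
    comes out of :func:`fit_hmm`.
    """

    initial_probs: np.ndarray
    transition_matrix: np.ndarray
    state_means: np.ndarray
    covariance: np.ndarray
    log_likelihood: float = float("nan")
    n_iter: int = 0
    converged: bool = True
    restart_seed: int | None = None
    loglik_trace: tuple[float, ...] = ()
    all_restart_traces: tuple[tuple[float, ...], ...] = field(default=(), repr=False)
    warnings_: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pi = np.asarray(self.initial_probs, dtype=float)
        A = np.asarray(self.transition_matrix, dtype=float)
        M = np.atleast_2d(np.asarray(self.state_means, dtype=float))
        S = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        object.__setattr__(self, "initial_probs", pi)
        object.__setattr__(self, "transition_matrix", A)
        object.__setattr__(self, "state_means", M)
        object.__setattr__(self, "covariance", S)
        K = pi.shape[0]
        if A.shape != (K, K):
            raise ValueError("transition matrix shape does not match initial_probs")
        if M.shape[0] != K:
            raise ValueError("state_means must have one row per state")
        if S.shape != (M.shape[1], M.shape[1]):
            raise ValueError("covariance shape does not match number of channels")
        if not np.allclose(A.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(pi.sum(), 1.0, atol=1e-10):
            raise ValueError("initial probabilities must sum to 1")
        if np.any(pi < -1e-12) or np.any(A < -1e-12):
            raise ValueError("probabilities must be non-negative")

    @property
    def n_states(self) -> int:
        return self.initial_probs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.state_means.shape[1]

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of A for eigenvalue 1, normalized to a simplex."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        p = np.real(v[:, i])
        p = np.abs(p)
        return p / p.sum()

    def to_dict(self) -> dict:
        return {
            "initial_probs": self.initial_probs.tolist(),
            "transition_matrix": self.transition_matrix.tolist(),
            "state_means": self.state_means.tolist(),
            "covariance": self.covariance.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "restart_seed": self.restart_seed,
            "loglik_trace": list(self.loglik_trace),
            "warnings": list(self.warnings_),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMModel":
        return cls(
            initial_probs=np.asarray(d["initial_probs"], float),
            transition_matrix=np.asarray(d["transition_matrix"], float),
            state_means=np.asarray(d["state_means"], float),
            covariance=np.asarray(d["covariance"], float),
            log_likelihood=float(d.get("log_likelihood", float("nan"))),
            n_iter=int(d.get("n_iter", 0)),
            converged=bool(d.get("converged", True)),
            restart_seed=d.get("restart_seed"),
            loglik_trace=tuple(d.get("loglik_trace", ())),
            warnings_=tuple(d.get("warnings", ())),
        )


@dataclass(frozen=True)
class StatePosterior:
    """Per-scan posterior: gamma (T, K) soft state assignments, xi (K, K)
    expected transition counts summed over the scan, and the scan
    log-likelihood under the model."""

    gamma: np.ndarray
    xi: np.ndarray
    log_likelihood: float

    @property
    def n_timepoints(self) -> int:
        return self.gamma.shape[0]

    @property
    def n_states(self) -> int:
        return self.gamma.shape[1]


def standardize_timecourse(raw: np.ndarray) -> np.ndarray:
    """Z-score each component's time course within the scan.

    Each column is shifted to mean 0 and scaled to unit sample SD (ddof=1).
    Constant columns are a hard error naming the offending component, since a
    zero-variance component cannot carry state information.
    """
    X = np.asarray(raw, dtype=float)
    if X.ndim != 2:
        raise ValueError("time course must be a T x C matrix")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 timepoints to standardize")
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant component column(s): {[f'comp_{i + 1}' for i in bad]}")
    return (X - X.mean(axis=0)) / sd


def concatenate_scans(scans: list[np.ndarray]) -> tuple[np.ndarray, list[int]]:
    """Stack scans along time; return the stacked matrix and boundary indices.

    ``boundaries`` has length n_scans + 1; scan ``i`` occupies rows
    ``boundaries[i]:boundaries[i+1]``.  Forward-backward restarts at each
    boundary, so no transitions are modelled across scans.
    """
    if not scans:
        raise ValueError("no scans to concatenate")
    C = scans[0].shape[1]
    boundaries = [0]
    for i, s in enumerate(scans):
        if s.ndim != 2 or s.shape[1] != C:
            raise ValueError(f"scan {i} has {s.shape[1] if s.ndim == 2 else '?'} components, expected {C}")
        boundaries.append(boundaries[-1] + s.shape[0])
    return np.vstack(scans), boundaries


def _gaussian_loglik(X: np.ndarray, means: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log N(x_t; mu_k, Sigma) for all t, k -> (T, K). Shared covariance."""
    C = cov.shape[0]
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular shared covariance; consider ridge regularization of Sigma"
        ) from e
    logdet = 2.0 * np.log(np.diag(L)).sum()
    const = -0.5 * (C * np.log(2.0 * np.pi) + logdet)
    # Mahalanobis distances via one triangular solve per state
    out = np.empty((X.shape[0], means.shape[0]))
    for k, mu in enumerate(means):
        z = np.linalg.solve(L, (X - mu).T)  # triangular in spirit; L is lower
        out[:, k] = const - 0.5 * np.einsum("ct,ct->t", z, z)
    return out


def _fb_batch(logB: np.ndarray, pi: np.ndarray, A: np.ndarray):
    """Scaled forward-backward on a batch of equal-length scans.

    logB: (S, T, K) emission log-likelihoods.  Returns gamma (S, T, K),
    xi (S, K, K) summed over time, and per-scan log-likelihood (S,).
    Scaling by per-timepoint normalizers keeps the recursion stable for
    T up to 1e5.
    """
    S, T, K = logB.shape
    m = logB.max(axis=2, keepdims=True)
    B = np.exp(logB - m)
    alpha = np.empty((S, T, K))
    c = np.empty((S, T))
    a = pi[None, :] * B[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    beta_t = np.ones((S, K))
    gamma = np.empty((S, T, K))
    gamma[:, T - 1] = alpha[:, T - 1]
    xi = np.zeros((S, K, K))
    for t in range(T - 2, -1, -1):
        bb = B[:, t + 1] * beta_t  # (S, K)
        xi += alpha[:, t, :, None] * A[None, :, :] * bb[:, None, :] / c[:, t + 1, None, None]
        beta_t = (bb @ A.T) / c[:, t + 1, None]
        gamma[:, t] = alpha[:, t] * beta_t
    ll = np.log(c).sum(axis=1) + m[:, :, 0].sum(axis=1)
    return gamma, xi, ll


def forward_backward(model: HMMModel, scan: np.ndarray) -> StatePosterior:
    """Posterior state probabilities and expected transition counts for one scan.

    Uses numerically scaled recursions; for K = 1 the posterior is degenerate
    and the log-likelihood reduces to the sum of Gaussian log-densities.
    """
    X = np.asarray(scan, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_channels:
        raise ValueError("scan shape does not match model channels")
    logB = _gaussian_loglik(X, model.state_means, model.covariance)
    gamma, xi, ll = _fb_batch(logB[None], model.initial_probs, model.transition_matrix)
    return StatePosterior(gamma=gamma[0], xi=xi[0], log_likelihood=float(ll[0]))


def _scan_groups(boundaries: list[int]) -> dict[int, list[tuple[int, int]]]:
    """Group scan row-ranges by scan length so forward-backward can be batched."""
    groups: dict[int, list[tuple[int, int]]] = {}
    for i in range(len(boundaries) - 1):
        a, b = boundaries[i], boundaries[i + 1]
        groups.setdefault(b - a, []).append((a, b))
    return groups


def _em_once(X, boundaries, K, max_iter, tol, ridge, restart_seed):
    N, C = X.shape
    groups = _scan_groups(boundaries)
    n_scans = len(boundaries) - 1

    km = KMeans(n_clusters=K, n_init=10, random_state=int(restart_seed) % (2**31 - 1))
    labels = km.fit_predict(X)
    means = km.cluster_centers_.copy()
    cov = np.cov(X.T, ddof=0) if C > 1 else np.atleast_2d(np.var(X))
    cov = cov + (1e-6 * np.trace(cov) / C) * np.eye(C)
    A = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(A, 0.9)
    A /= A.sum(axis=1, keepdims=True)
    pi = np.full(K, 1.0 / K)
    del labels

    XtX = X.T @ X  # constant across iterations: sum_t x_t x_t^T
    trace: list[float] = []
    warns: list[str] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logB_all = _gaussian_loglik(X, means, cov)
        ll_total = 0.0
        pi_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        Nk = np.zeros(K)
        Sx = np.zeros((K, C))
        for T_len, spans in groups.items():
            logB = np.stack([logB_all[a:b] for a, b in spans])
            gamma, xi, ll = _fb_batch(logB, pi, A)
            ll_total += float(ll.sum())
            pi_acc += gamma[:, 0, :].sum(axis=0)
            xi_acc += xi.sum(axis=0)
            g2 = gamma.reshape(-1, K)
            Nk += g2.sum(axis=0)
            Xg = np.vstack([X[a:b] for a, b in spans])
            Sx += g2.T @ Xg
        trace.append(ll_total)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
            converged = True
            break
        # M-step
        pi = pi_acc / n_scans
        pi = np.clip(pi, 1e-12, None)
        pi /= pi.sum()
        rows = xi_acc.sum(axis=1, keepdims=True)
        A = np.where(rows > 0, xi_acc / np.where(rows > 0, rows, 1.0), 1.0 / K)
        A = np.clip(A, 1e-12, None)
        A /= A.sum(axis=1, keepdims=True)
        if np.any(Nk < 1.0):
            warns.append(f"empty state(s) at iteration {it}: {np.flatnonzero(Nk < 1.0).tolist()}")
        means = Sx / np.clip(Nk, 1e-12, None)[:, None]
        # pooled covariance: sum_t x x^T is XtX because gamma rows sum to 1
        cross = means.T @ Sx
        cov = (XtX - cross - cross.T + (means.T * Nk) @ means) / N
        cov = 0.5 * (cov + cov.T)
        cov = cov + (ridge * np.trace(cov) / C) * np.eye(C)
    if not converged:
        warns.append(f"EM did not converge in {max_iter} iterations")
    return HMMModel(
        initial_probs=pi,
        transition_matrix=A,
        state_means=means,
        covariance=cov,
        log_likelihood=trace[-1],
        n_iter=it,
        converged=converged,
        restart_seed=int(restart_seed),
        loglik_trace=tuple(trace),
        warnings_=tuple(warns),
    )


def fit_hmm(
    data: np.ndarray,
    boundaries: list[int],
    K: int,
    *,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
    ridge: float = 1e-6,
) -> HMMModel:
    """Fit the shared-covariance Gaussian HMM by EM with random restarts.

    ``data`` is the stacked standardized time-course matrix with scan
    ``boundaries`` from :func:`concatenate_scans`.  Each restart initializes
    state means by k-means, the transition matrix with diagonal 0.9, uniform
    initial probabilities and the pooled sample covariance; the restart with
    the highest final log-likelihood wins.  The M-step pools the covariance
    across states and adds a small ridge (``ridge * trace(Sigma)/C``) to the
    diagonal for conditioning.  Deterministic given ``seed``.
    """
    X = np.asarray(data, dtype=float)
    if K < 2:
        raise ValueError("fit_hmm requires K >= 2")
    if boundaries[0] != 0 or boundaries[-1] != X.shape[0]:
        raise ValueError("boundaries do not span the stacked data")
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best: HMMModel | None = None
    traces = []
    for rs in restart_seeds:
        model = _em_once(X, list(boundaries), K, max_iter, tol, ridge, rs)
        traces.append(model.loglik_trace)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    assert best is not None
    if not best.converged:
        warnings.warn("best HMM restart did not converge; model returned anyway", stacklevel=2)
    return replace(best, all_restart_traces=tuple(traces))


def match_states(means_ref: np.ndarray, means_other: np.ndarray) -> np.ndarray:
    """Hungarian matching of states by Euclidean distance between mean vectors.

    Returns ``perm`` such that state ``perm[k]`` of the other model corresponds
    to state ``k`` of the reference.  State labels are arbitrary across runs;
    every cross-run comparison goes through this matching.
    """
    D = cdist(np.atleast_2d(means_ref), np.atleast_2d(means_other))
    rows, cols = linear_sum_assignment(D)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


def brute_force_loglik(model: HMMModel, scan: np.ndarray) -> float:
    """Exhaustive path-enumeration log-likelihood (oracle for tiny K, T).

    Sums path-probability times emission likelihood over all K**T state paths.
    Intended for validation only; refuses more than ~1e6 paths.
    """
    X = np.asarray(scan, dtype=float)
    T = X.shape[0]
    K = model.n_states
    if K**T > 1_000_000:
        raise ValueError("path enumeration too large")
    logB = _gaussian_loglik(X, model.state_means, model.covariance)
    logpi = np.log(model.initial_probs)
    logA = np.log(model.transition_matrix)
    terms = []
    for path in itertools.product(range(K), repeat=T):
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        terms.append(lp)
    terms = np.asarray(terms)
    m = terms.max()
    return float(m + np.log(np.exp(terms - m).sum()))
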