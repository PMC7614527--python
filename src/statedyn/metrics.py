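"""Temporal-dynamics metrics derived from per-scan state posteriors.

Fractional occupancy (the proportion of scan time each state is active),
switching rate (between-state transitions per second of scan time, adjusted
for repetition time), the per-subject row-stochastic transition/persistence
matrix, and state mean-activation maps.  All metrics are computed from the
soft posteriors (gamma, xi) rather than a hard Viterbi path; a hard-path
sensitivity variant can be obtained by passing a one-hot gamma.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import HMMModel, StatePosterior

__all__ = [
    "DynamicsMetrics",
    "fractional_occupancy",
    "switching_rate",
    "subject_transition_matrix",
    "mean_activation_map",
    "scan_metrics",
    "metrics_table",
]


@dataclass(frozen=True)
class DynamicsMetrics:
    """Per-scan dynamics summary: FO simplex, switching rate (s^-1), and the
    row-stochastic transition matrix (off-diagonal = transition probabilities,
    diagonal = persistence probabilities)."""

    fractional_occupancy: np.ndarray
    switching_rate: float
    transition_matrix: np.ndarray
    repetition_time: float
    flagged_rows: tuple[int, ...] = ()


def fractional_occupancy(post: StatePosterior) -> np.ndarray:
    """FO_k = (1/T) sum_t gamma_tk; lies on the K-simplex."""
    gamma = np.asarray(post.gamma, dtype=float)
    return gamma.mean(axis=0)


def switching_rate(post: StatePosterior, repetition_time: float) -> float:
    """Expected between-state transitions per second of scan time.

    SR = (sum of off-diagonal xi) / ((T - 1) * TR).  The (T - 1) transition
    opportunities span (T - 1) * TR seconds, and dividing by seconds makes
    rates comparable across sites with slightly different repetition times.
    """
    if repetition_time <= 0:
        raise ValueError("repetition_time must be positive")
    if post.n_timepoints < 2:
        raise ValueError("need at least 2 timepoints for a switching rate")
    xi = np.asarray(post.xi, dtype=float)
    off = xi.sum() - np.trace(xi)
    return float(off / ((post.n_timepoints - 1) * repetition_time))


def subject_transition_matrix(
    post: StatePosterior, group_model: HMMModel | None = None
) -> tuple[np.ndarray, tuple[int, ...]]:
    """Row-normalized expected transition counts for one scan.

    Rows with (numerically) zero expected outgoing mass carry no information
    about that state's transitions; they are replaced by the group model's
    corresponding row of A when available (uniform otherwise) and their
    indices are returned as flags.
    """
    xi = np.asarray(post.xi, dtype=float)
    K = xi.shape[0]
    rows = xi.sum(axis=1)
    flagged = tuple(int(i) for i in np.flatnonzero(rows <= 1e-10))
    P = np.empty_like(xi)
    for i in range(K):
        if i in flagged:
            if group_model is not None:
                P[i] = group_model.transition_matrix[i]
            else:
                P[i] = 1.0 / K
        else:
            P[i] = xi[i] / rows[i]
    return P, flagged


def mean_activation_map(component_maps: np.ndarray, model: HMMModel) -> np.ndarray:
    """State activation maps: weight component maps by the state Gaussian means.

    ``component_maps`` is V x C (one column per ICA component); the result is
    V x K with ``map_k = component_maps @ mu_k``.
    """
    maps = np.asarray(component_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[1] != model.n_channels:
        raise ValueError(
            f"component_maps has {maps.shape[-1]} columns, model expects {model.n_channels}"
        )
    return maps @ model.state_means.T


def scan_metrics(
    post: StatePosterior,
    repetition_time: float,
    group_model: HMMModel | None = None,
) -> DynamicsMetrics:
    P, flagged = subject_transition_matrix(post, group_model)
    return DynamicsMetrics(
        fractional_occupancy=fractional_occupancy(post),
        switching_rate=switching_rate(post, repetition_time),
        transition_matrix=P,
        repetition_time=float(repetition_time),
        flagged_rows=flagged,
    )


def metrics_table(scan_ids: list[str], metrics: list[DynamicsMetrics]) -> pd.DataFrame:
    """Tidy per-scan metrics table: FO_1..FO_K, SR, and the flattened
    transition matrix in row-major order as P_i_j columns."""
    if len(scan_ids) != len(metrics):
        raise ValueError("scan_ids and metrics length mismatch")
    K = metrics[0].fractional_occupancy.shape[0]
    rows = []
    for sid, m in zip(scan_ids, metrics):
        row: dict[str, object] = {"scan_id": sid}
        for k in range(K):
            row[f"FO_{k + 1}"] = m.fractional_occupancy[k]
        row["SR"] = m.switching_rate
        for i in range(K):
            for j in range(K):
                row[f"P_{i + 1}_{j + 1}"] = m.transition_matrix[i, j]
        rows.append(row)
    return pd.DataFrame(rows)
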