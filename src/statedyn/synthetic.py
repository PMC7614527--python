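"""Synthetic cohorts with known brain-state dynamics and planted group effects.

The generator emulates the structure of a multi-site familial-FTD imaging
study: per-scan ICA component time courses driven by a hidden Markov chain
with a shared-covariance Gaussian observation model, a scan-level metadata
table (diagnostic group, converter flag, age, sex, site, mutation,
repetition time, motion-QC indices), and a longitudinal visits table of
cognitive scores.

Group effects are planted mechanistically, through the transition matrix
rather than through observation means: symptomatic subjects (and, at a
configurable fractional dose, presymptomatic converters) receive an
increment to the persistence probability of a designated target state,
which raises that state's stationary occupancy.  Annual cognitive decline
is linked to the subject's true target-state occupancy for symptomatic
subjects, so the two-step longitudinal model has a known signal to recover.
Everything is reproducible bit-for-bit from the spec's seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hmm import HMMModel
from .qc import MotionIndices

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "SyntheticCohort",
    "sample_ground_truth",
    "simulate_timecourse",
    "sample_state_path",
    "sample_state_paths",
    "shifted_transition_matrix",
    "simulate_cohort",
    "write_cohort",
]

GROUPS = ("noncarrier", "presymptomatic", "symptomatic")
_MUTATIONS = ("C9orf72", "GRN", "MAPT", "TBK1")
_MUTATION_P = (0.37, 0.42, 0.19, 0.02)


def sample_ground_truth(
    K: int,
    C: int,
    persistence: float,
    seed: int,
    *,
    mean_separation: float = 2.0,
) -> HMMModel:
    """Draw a ground-truth K-state HMM with C channels.

    The transition matrix has ``persistence`` on the diagonal with the
    remaining mass split evenly off-diagonal; the initial distribution is
    uniform (the chain's stationary distribution).  State means are drawn
    from a standard normal and rescaled until every pair is at least
    ``mean_separation`` z-units apart.  The shared covariance is built from
    a random orthogonal basis with eigenvalues in [0.5, 2], so its condition
    number is at most 4 (well under the well-conditioning requirement).
    """
    if not 0.0 < persistence < 1.0:
        raise ValueError("persistence must lie in (0, 1)")
    if K < 2:
        raise ValueError("need at least 2 states")
    rng = np.random.default_rng(seed)
    A = np.full((K, K), (1.0 - persistence) / (K - 1))
    np.fill_diagonal(A, persistence)
    pi = np.full(K, 1.0 / K)
    M = rng.standard_normal((K, C))
    for _ in range(100):
        d = np.sqrt(((M[:, None, :] - M[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= mean_separation:
            break
        M *= 1.2
    Q, _ = np.linalg.qr(rng.standard_normal((C, C)))
    eig = np.linspace(0.5, 2.0, C)
    Sigma = (Q * eig) @ Q.T
    Sigma = 0.5 * (Sigma + Sigma.T)
    return HMMModel(initial_probs=pi, transition_matrix=A, state_means=M, covariance=Sigma)


def shifted_transition_matrix(A: np.ndarray, target_state: int, shift: float) -> np.ndarray:
    """Increment the persistence probability of ``target_state`` (0-based).

    The target row's off-diagonal mass is rescaled to keep the row on the
    simplex; other rows are untouched.
    """
    A = np.asarray(A, dtype=float).copy()
    K = A.shape[0]
    p_new = A[target_state, target_state] + shift
    if not 0.0 <= p_new < 1.0:
        raise ValueError(f"persistence after shift must be in [0, 1); got {p_new}")
    off = 1.0 - A[target_state, target_state]
    if off > 0:
        A[target_state] *= (1.0 - p_new) / off
    else:
        A[target_state] = (1.0 - p_new) / (K - 1)
    A[target_state, target_state] = p_new
    return A


def sample_state_path(pi: np.ndarray, A: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
    """Sample a length-T state path (0-based) from pi then A."""
    cdf0 = np.cumsum(pi)
    cdfA = np.cumsum(A, axis=1)
    path = np.empty(T, dtype=int)
    path[0] = int(np.searchsorted(cdf0, rng.random()))
    for t in range(1, T):
        path[t] = int(np.searchsorted(cdfA[path[t - 1]], rng.random()))
    return path


def sample_state_paths(
    pi: np.ndarray, A: np.ndarray, n_subjects: int, T: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n_subjects`` independent length-T paths (0-based), vectorized.

    All subjects share the same chain; the time loop advances every subject
    at once, which is what makes large calibration simulations affordable.
    """
    cdfA = np.cumsum(A, axis=1)
    paths = np.empty((n_subjects, T), dtype=int)
    paths[:, 0] = np.searchsorted(np.cumsum(pi), rng.random(n_subjects))
    for t in range(1, T):
        u = rng.random((n_subjects, 1))
        paths[:, t] = (u <= cdfA[paths[:, t - 1]]).argmax(axis=1)
    return paths


def simulate_timecourse(
    hmm: HMMModel, T: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one scan: (state path with 1-based labels, raw T x C matrix).

    Observations are drawn from the active state's Gaussian with the shared
    covariance.  The returned time course is NOT standardized; per-scan
    z-scoring is an explicit downstream step.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    path0 = sample_state_path(hmm.initial_probs, hmm.transition_matrix, T, rng)
    L = np.linalg.cholesky(hmm.covariance)
    X = hmm.state_means[path0] + rng.standard_normal((T, hmm.n_channels)) @ L.T
    return path0 + 1, X


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the structure of a multi-site genetic-FTD study: three
    diagnostic groups with symptomatic subjects markedly older than
    presymptomatic carriers, a small number of presymptomatic converters,
    a handful of scan sites with slightly different repetition times, annual
    cognitive visits, and a ~10% rate of motion-QC failures.  The planted
    persistence shift of 0.078 at base persistence 0.8 raises the target
    state's stationary occupancy by ~0.08 in symptomatic subjects; converters
    receive the shift at the fractional ``converter_dose``.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"noncarrier": 120, "presymptomatic": 120, "symptomatic": 60}
    )
    n_converters: int = 14
    n_states: int = 6
    n_channels: int = 24
    T_per_scan: int = 300
    persistence: float = 0.8
    mean_separation: float = 2.0
    repetition_times: tuple[float, ...] = (2.0, 2.2, 2.4, 2.5)  # one per site
    age_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "noncarrier": (48.0, 13.0),
            "presymptomatic": (45.0, 12.0),
            "symptomatic": (63.0, 8.2),
        }
    )
    target_state: int = 2  # 1-based label of the state carrying the planted effect
    effect_occupancy_shift: float = 0.078
    converter_dose: float = 0.5
    slope_link_beta: float = -8.0  # score points / year per unit occupancy deviation
    base_slope: dict[str, float] = field(
        default_factory=lambda: {"noncarrier": 0.0, "presymptomatic": -0.05, "symptomatic": -1.5}
    )
    slope_sd: dict[str, float] = field(
        default_factory=lambda: {"noncarrier": 0.1, "presymptomatic": 0.1, "symptomatic": 0.5}
    )
    score_intercept: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "noncarrier": (29.0, 1.0),
            "presymptomatic": (29.0, 1.0),
            "symptomatic": (21.0, 4.0),
        }
    )
    site_intercept_sd: float = 0.3  # per-site shift of the cognitive score
    noise_sd: float = 1.0
    n_visits: int = 4
    qc_exceed_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if sum(self.group_sizes.values()) == 0:
            raise ValueError("empty cohort")
        for g in self.group_sizes:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        if not 0 <= self.persistence + self.effect_occupancy_shift < 1:
            raise ValueError("persistence after shift must lie in [0, 1)")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        if not 1 <= self.target_state <= self.n_states:
            raise ValueError("target_state out of range")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["repetition_times"] = list(d["repetition_times"])
        d["age_model"] = {k: list(v) for k, v in d["age_model"].items()}
        d["score_intercept"] = {k: list(v) for k, v in d["score_intercept"].items()}
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass(frozen=True)
class SyntheticSubject:
    subject_id: str
    group: str
    converter: bool
    true_state_path: np.ndarray  # 1-based labels
    timecourse: np.ndarray  # raw T x C
    metadata_row: dict
    motion: MotionIndices
    visits: pd.DataFrame


@dataclass(frozen=True)
class SyntheticCohort:
    spec: CohortSpec
    ground_truth: HMMModel
    subjects: tuple[SyntheticSubject, ...]

    @property
    def cohort_table(self) -> pd.DataFrame:
        return pd.DataFrame([s.metadata_row for s in self.subjects])

    @property
    def visits_table(self) -> pd.DataFrame:
        return pd.concat([s.visits for s in self.subjects], ignore_index=True)

    def true_target_occupancy(self) -> pd.Series:
        """Empirical occupancy of the target state on each subject's true path."""
        t = self.spec.target_state
        return pd.Series(
            {s.subject_id: float(np.mean(s.true_state_path == t)) for s in self.subjects},
            name="true_target_occupancy",
        )


def _draw_motion(rng: np.random.Generator, exceed: bool) -> MotionIndices:
    # clean draws sit comfortably below the default bounds (5 %, 3 mm, 5 a.u.)
    bounds = {"max_spike_percentage": 5.0, "max_framewise_displacement": 3.0, "max_dvars": 5.0}
    vals = {k: float(b * rng.uniform(0.1, 0.8)) for k, b in bounds.items()}
    if exceed:
        which = list(bounds)[int(rng.integers(0, 3))]
        vals[which] = float(bounds[which] * rng.uniform(1.05, 1.5))
    vals["mean_framewise_displacement"] = float(rng.uniform(0.02, 0.3))
    return MotionIndices(**vals)


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full synthetic cohort defined by ``spec``.

    Deterministic given ``spec.seed``: the same spec always produces
    byte-identical tables and time courses.
    """
    rng = np.random.default_rng(spec.seed)
    truth = sample_ground_truth(
        spec.n_states,
        spec.n_channels,
        spec.persistence,
        seed=int(rng.integers(0, 2**31 - 1)),
        mean_separation=spec.mean_separation,
    )
    n_sites = len(spec.repetition_times)
    site_shift = rng.normal(0.0, spec.site_intercept_sd, size=n_sites)
    chol = np.linalg.cholesky(truth.covariance)
    target0 = spec.target_state - 1

    subjects: list[SyntheticSubject] = []
    idx = 0
    for group in GROUPS:
        n_g = spec.group_sizes.get(group, 0)
        n_conv = spec.n_converters if group == "presymptomatic" else 0
        if n_conv > n_g:
            raise ValueError("more converters than presymptomatic subjects")
        for j in range(n_g):
            idx += 1
            sid = f"sub{idx:04d}"
            converter = group == "presymptomatic" and j < n_conv
            dose = (
                1.0
                if group == "symptomatic"
                else (spec.converter_dose if converter else 0.0)
            )
            A_subj = shifted_transition_matrix(
                truth.transition_matrix, target0, dose * spec.effect_occupancy_shift
            )
            path0 = sample_state_path(truth.initial_probs, A_subj, spec.T_per_scan, rng)
            X = truth.state_means[path0] + rng.standard_normal(
                (spec.T_per_scan, spec.n_channels)
            ) @ chol.T
            site = int(rng.integers(0, n_sites))
            mu_age, sd_age = spec.age_model[group]
            age = float(np.clip(rng.normal(mu_age, sd_age), 18.0, 95.0))
            sex = "F" if rng.random() < 0.5 else "M"
            mutation = (
                "none"
                if group == "noncarrier"
                else _MUTATIONS[int(np.searchsorted(np.cumsum(_MUTATION_P), rng.random()))]
            )
            motion = _draw_motion(rng, exceed=rng.random() < spec.qc_exceed_fraction)
            occ_dev = float(np.mean(path0 == target0) - 1.0 / spec.n_states)
            link = spec.slope_link_beta * occ_dev if group == "symptomatic" else 0.0
            slope = spec.base_slope[group] + rng.normal(0.0, spec.slope_sd[group]) + link
            ic_mu, ic_sd = spec.score_intercept[group]
            intercept = rng.normal(ic_mu, ic_sd) + site_shift[site]
            times = np.arange(spec.n_visits, dtype=float)
            scores = np.clip(
                intercept + slope * times + rng.normal(0.0, spec.noise_sd, spec.n_visits),
                0.0,
                30.0,
            )
            visits = pd.DataFrame(
                {
                    "subject_id": sid,
                    "years_from_baseline": times,
                    "cognition": np.round(scores, 6),
                }
            )
            row = {
                "scan_id": f"{sid}_s1",
                "subject_id": sid,
                "group": group,
                "converter": converter,
                "age": round(age, 3),
                "sex": sex,
                "site": f"site{site + 1}",
                "mutation": mutation,
                "repetition_time": spec.repetition_times[site],
                "n_volumes": spec.T_per_scan,
                "visit_index": 0,
                "max_spike_percentage": round(motion.max_spike_percentage, 6),
                "max_framewise_displacement": round(motion.max_framewise_displacement, 6),
                "max_dvars": round(motion.max_dvars, 6),
                "mean_framewise_displacement": round(motion.mean_framewise_displacement, 6),
            }
            subjects.append(
                SyntheticSubject(
                    subject_id=sid,
                    group=group,
                    converter=converter,
                    true_state_path=path0 + 1,
                    timecourse=X,
                    metadata_row=row,
                    motion=motion,
                    visits=visits,
                )
            )
    return SyntheticCohort(spec=spec, ground_truth=truth, subjects=tuple(subjects))


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write time-course TSVs, cohort CSV, visits CSV, and the spec JSON."""
    from .io import write_timecourse  # local import to avoid a cycle

    out = Path(out_dir)
    tc_dir = out / "timecourses"
    tc_dir.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        write_timecourse(tc_dir / f"{s.metadata_row['scan_id']}.tsv", s.timecourse)
    cohort_csv = out / "cohort.csv"
    visits_csv = out / "visits.csv"
    cohort.cohort_table.to_csv(cohort_csv, index=False, float_format="%.10g")
    cohort.visits_table.to_csv(visits_csv, index=False, float_format="%.10g")
    spec_json = out / "cohort_spec.json"
    spec_json.write_text(cohort.spec.to_json() + "\n")
    return {
        "timecourse_dir": tc_dir,
        "cohort_csv": cohort_csv,
        "visits_csv": visits_csv,
        "spec_json": spec_json,
    }
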