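"""File formats and pipeline configuration.

All interchange is plain text: per-scan time-course TSVs (header
``comp_1..comp_C``), a scan-level cohort CSV, a long-format visits CSV, and
JSON for model and configuration serialization.  Floating-point output uses
a fixed ``%.10g`` format so reruns are byte-reproducible.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hmm import HMMModel
from .qc import MOTION_COLUMNS

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_cohort",
    "read_visits",
    "write_model",
    "read_model",
    "PipelineConfig",
    "CONFIG_SCHEMA",
]

FLOAT_FMT = "%.10g"

COHORT_REQUIRED = (
    "scan_id",
    "subject_id",
    "group",
    "converter",
    "age",
    "sex",
    "site",
    "repetition_time",
    "n_volumes",
    "visit_index",
) + MOTION_COLUMNS

GROUP_VALUES = {"noncarrier", "presymptomatic", "symptomatic"}


def read_timecourse(path: str | Path) -> np.ndarray:
    """Read one scan's T x C component time-course TSV.

    The header must be ``comp_1 .. comp_C`` in order; every body cell must be
    a finite number.  Errors name the offending line/column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as e:
        raise ValueError(f"{path.name}: ragged or malformed TSV ({e})") from e
    expected = [f"comp_{i + 1}" for i in range(df.shape[1])]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path.name}: header must be {expected[:2]}...; got {list(df.columns)[:3]}"
        )
    arr = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if bad.size:
            raise ValueError(
                f"{path.name}: non-numeric or missing value at data row {bad[0] + 1}, column {col}"
            )
        arr[:, j] = vals.to_numpy(dtype=float)
    return arr


def write_timecourse(path: str | Path, X: np.ndarray) -> None:
    X = np.asarray(X, dtype=float)
    header = "\t".join(f"comp_{i + 1}" for i in range(X.shape[1]))
    np.savetxt(path, X, delimiter="\t", header=header, comments="", fmt=FLOAT_FMT)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate the scan-level cohort table."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad = set(df["group"].astype(str)) - GROUP_VALUES
    if bad:
        raise ValueError(f"unknown group values: {sorted(bad)}")
    if df["scan_id"].duplicated().any():
        dup = df.loc[df["scan_id"].duplicated(), "scan_id"].iloc[0]
        raise ValueError(f"duplicate scan_id: {dup}")
    if isinstance(df["converter"].dtype, object) or df["converter"].dtype == object:
        df["converter"] = df["converter"].astype(str).str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
    df["converter"] = df["converter"].astype(bool)
    return df


def read_visits(path: str | Path, cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate the longitudinal visits table.

    Requires subject_id, years_from_baseline and at least one outcome column;
    rejects duplicate (subject, time) rows and, when a cohort table is given,
    visits for subjects absent from it.
    """
    df = pd.read_csv(path)
    for c in ("subject_id", "years_from_baseline"):
        if c not in df.columns:
            raise ValueError(f"visits table missing column {c!r}")
    outcomes = [c for c in df.columns if c not in ("subject_id", "years_from_baseline")]
    if not outcomes:
        raise ValueError("visits table has no outcome columns")
    dup = df.duplicated(subset=["subject_id", "years_from_baseline"])
    if dup.any():
        r = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate visit: subject {r['subject_id']} at t={r['years_from_baseline']}"
        )
    if cohort is not None:
        known = set(cohort["subject_id"].astype(str))
        orphans = sorted(set(df["subject_id"].astype(str)) - known)
        if orphans:
            raise ValueError(f"visits reference unknown subjects: {orphans[:5]}")
    return df


def write_model(path: str | Path, model: HMMModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n")


def read_model(path: str | Path) -> HMMModel:
    return HMMModel.from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

# Defaults that mirror the study design this pipeline implements are noted
# as such; everything is overridable from the JSON config.
CONFIG_SCHEMA: dict[str, str] = {
    "timecourse_dir": "directory of per-scan component time-course TSVs",
    "cohort_csv": "scan-level cohort metadata CSV",
    "visits_csv": "longitudinal visits CSV",
    "output_dir": "directory for all pipeline outputs",
    "n_states": "number of HMM brain states K (default 6, the study-standard model order)",
    "qc_thresholds": "upper bounds per motion index; null deactivates an index",
    "hmm_n_restarts": "EM restarts (default 5)",
    "hmm_max_iter": "maximum EM iterations per restart (default 500)",
    "hmm_tol": "relative log-likelihood convergence tolerance (default 1e-5)",
    "seed": "master seed for every stochastic stage",
    "pca_alpha": "alpha of the compositional transform (default 1, the linear case)",
    "n_perm": "permutations for the transition-matrix test (default 5000, study-standard)",
    "fdr_level": "false-discovery-rate level (default 0.05, study-standard)",
    "fwe_level": "family-wise-error level for the permutation test (default 0.05)",
    "floor_definitions": "per-outcome floor/ceiling values for the longitudinal stage",
    "simulate": "CohortSpec overrides for the optional simulate stage (null to disable)",
}


@dataclass
class PipelineConfig:
    timecourse_dir: str = "timecourses"
    cohort_csv: str = "cohort.csv"
    visits_csv: str = "visits.csv"
    output_dir: str = "results"
    n_states: int = 6
    qc_thresholds: dict = field(
        default_factory=lambda: {
            "max_spike_percentage": 5.0,
            "max_framewise_displacement": 3.0,
            "max_dvars": 5.0,
            "mean_framewise_displacement": None,
        }
    )
    hmm_n_restarts: int = 5
    hmm_max_iter: int = 500
    hmm_tol: float = 1e-5
    seed: int = 0
    pca_alpha: float = 1.0
    n_perm: int = 5000
    fdr_level: float = 0.05
    fwe_level: float = 0.05
    floor_definitions: dict = field(default_factory=lambda: {"cognition": {"floor": 0.0}})
    simulate: dict | None = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        for name in ("fdr_level", "fwe_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())
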