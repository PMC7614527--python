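"""Two-step prediction of longitudinal cognitive decline.

Stage one fits a random-intercept, random-slope mixed model per outcome
(``score ~ time + (time | subject)``) across all retained participants and
extracts each subject's annual rate of change as the fixed slope plus the
subject's conditional (shrunken) random-slope prediction.  Stage two
regresses these slopes on baseline component scores with baseline age, sex,
and site as covariates of no interest, optionally interacting the component
score with age and with diagnostic group.  Subjects whose baseline value
sits at an outcome's floor (or ceiling, for timed tests capped at a
maximum) are removed for that outcome only before stage one.
All continuous stage-two variables are z-scored within the modelled sample,
so reported betas are standardized.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

__all__ = [
    "FloorDefinition",
    "PredictionResult",
    "remove_floor",
    "estimate_slopes",
    "predict_decline",
    "encode_site",
    "PREDICTION_FORMS",
]

PREDICTION_FORMS = ("comp", "comp_x_age", "comp_x_age_x_group")


@dataclass(frozen=True)
class FloorDefinition:
    """Floor and/or ceiling for one outcome; ``None`` disables that side."""

    floor: float | None = None
    ceiling: float | None = None


@dataclass(frozen=True)
class PredictionResult:
    """Stage-two result for one outcome and model form.

    ``std_beta``/``t_stat``/``p_value`` refer to the headline term of the
    form (the component main effect, the component-by-age interaction, or
    the three-way component-by-age-by-group interaction); ``terms`` holds
    every standardized coefficient.
    """

    outcome: str
    form: str
    headline_term: str
    std_beta: float
    t_stat: float
    p_value: float
    p_adjusted: float | None
    n: int
    terms: dict[str, tuple[float, float, float]]  # name -> (beta, t, p)


def remove_floor(
    visits: pd.DataFrame,
    floor_definitions: dict[str, FloorDefinition],
    *,
    subject_col: str = "subject_id",
    time_col: str = "years_from_baseline",
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Per-outcome removal of subjects at floor/ceiling at baseline.

    A subject is removed for an outcome iff their baseline (earliest-visit)
    value is at or beyond the defined floor or ceiling; the subject is kept
    for every other outcome.  Returns (outcome -> filtered visits table,
    removal report with counts per outcome).
    """
    reports = []
    out: dict[str, pd.DataFrame] = {}
    for outcome, fd in floor_definitions.items():
        if outcome not in visits.columns:
            raise ValueError(f"unknown outcome {outcome!r}")
        v = visits.dropna(subset=[outcome])
        base = v.sort_values(time_col, kind="mergesort").groupby(subject_col).head(1)
        removed = pd.Series(False, index=base[subject_col])
        if fd.floor is not None:
            removed |= pd.Series(
                (base[outcome] <= fd.floor).to_numpy(), index=base[subject_col]
            )
        if fd.ceiling is not None:
            removed |= pd.Series(
                (base[outcome] >= fd.ceiling).to_numpy(), index=base[subject_col]
            )
        drop = set(removed[removed].index)
        out[outcome] = v[~v[subject_col].isin(drop)].reset_index(drop=True)
        reports.append({"outcome": outcome, "n_removed": len(drop), "n_kept": base.shape[0] - len(drop)})
    return out, pd.DataFrame(reports)


def estimate_slopes(
    visits: pd.DataFrame,
    outcome: str,
    *,
    subject_col: str = "subject_id",
    time_col: str = "years_from_baseline",
) -> pd.DataFrame:
    """Per-subject annual rates of change from a random-slope mixed model.

    The model is ``outcome ~ time`` with correlated random intercepts and
    slopes by subject, fit by REML across all retained participants.  Each
    subject's slope is the fixed slope plus the conditional (shrunken)
    random-slope prediction — single-visit subjects are pulled toward the
    population slope.  If the random-effect covariance is singular the model
    is refit with independent (diagonal) random effects, with a warning.
    Returns a table with subject_id, intercept, slope, slope_se, n_visits.
    """
    v = visits.dropna(subset=[outcome]).copy()
    n_multi = v.groupby(subject_col)[time_col].nunique()
    if (n_multi >= 2).sum() == 0:
        raise ValueError("no subject has two or more visits; slopes are unidentified")
    v["_t"] = v[time_col].astype(float)
    model = MixedLM.from_formula(
        f"{outcome} ~ _t", groups=subject_col, re_formula="~_t", data=v
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
        ev = np.linalg.eigvalsh(res.cov_re)
        if np.any(ev < 1e-10 * max(ev.max(), 1e-12)) or not res.converged:
            free = MixedLMParams.from_components(
                fe_params=np.ones(2), cov_re=np.eye(2)
            )
            res = model.fit(reml=True, free=free)
            warnings.warn(
                "singular random-effect covariance; refit with diagonal covariance",
                stacklevel=2,
            )
    fe_int = float(res.fe_params.iloc[0])
    fe_slope = float(res.fe_params.iloc[1])
    G = np.asarray(res.cov_re)
    sigma2 = float(res.scale)
    rows = []
    re = res.random_effects
    for sid, grp in v.groupby(subject_col, sort=True):
        r = re.get(sid)
        b_int = float(r.iloc[0]) if r is not None else 0.0
        b_slope = float(r.iloc[1]) if r is not None else 0.0
        # conditional covariance of the BLUP: (Z'Z/sigma2 + G^-1)^-1
        Z = np.column_stack([np.ones(len(grp)), grp["_t"].to_numpy(dtype=float)])
        try:
            cond = np.linalg.inv(Z.T @ Z / sigma2 + np.linalg.inv(G))
            slope_se = float(np.sqrt(max(cond[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            slope_se = float("nan")
        rows.append(
            {
                "subject_id": sid,
                "intercept": fe_int + b_int,
                "slope": fe_slope + b_slope,
                "slope_se": slope_se,
                "n_visits": int(len(grp)),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["fixed_slope"] = fe_slope
    out.attrs["fixed_intercept"] = fe_int
    return out


def encode_site(site: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect dummy coding for scan site (reference = first level).

    With a single site the encoding is empty — the columns are dropped
    silently, matching the degenerate single-centre design.
    """
    levels = sorted(map(str, site.astype(str).unique()))
    if len(levels) < 2:
        return np.empty((len(site), 0)), []
    s = site.astype(str)
    cols = [(s == lev).to_numpy(dtype=float) for lev in levels[1:]]
    return np.column_stack(cols), [f"site[{lev}]" for lev in levels[1:]]


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (x - x.mean()) / sd


def predict_decline(
    data: pd.DataFrame,
    form: str,
    *,
    outcome_name: str = "",
    slope_col: str = "slope",
    comp_col: str = "comp",
    age_col: str = "age",
    sex_col: str = "sex",
    site_col: str = "site",
    group_col: str = "group",
) -> PredictionResult:
    """Stage-two regression of decline slopes on baseline component scores.

    ``form`` is one of ``comp`` (component main effect plus covariates),
    ``comp_x_age`` (adds the component-by-age interaction) and
    ``comp_x_age_x_group`` (full three-way factorial with a binary group).
    Slope, component score and age are z-scored within the modelled sample,
    so the reported coefficients are standardized betas.
    """
    if form not in PREDICTION_FORMS:
        raise ValueError(f"unknown form {form!r}; use one of {PREDICTION_FORMS}")
    d = data.dropna(subset=[slope_col, comp_col, age_col]).reset_index(drop=True)
    y = _zscore(d[slope_col].to_numpy(dtype=float))
    comp = _zscore(d[comp_col].to_numpy(dtype=float))
    age = _zscore(d[age_col].to_numpy(dtype=float))
    sex = d[sex_col]
    sex = (
        sex.to_numpy(dtype=float)
        if sex.dtype.kind in "ifb"
        else sex.astype(str).str.upper().map({"F": 0.0, "M": 1.0}).to_numpy(dtype=float)
    )
    S, site_names = encode_site(d[site_col]) if site_col in d.columns else (np.empty((len(d), 0)), [])
    cols: list[np.ndarray] = [np.ones(len(d)), comp, age, sex]
    names: list[str] = ["intercept", "comp", "age", "sex"]
    if form in ("comp_x_age", "comp_x_age_x_group"):
        cols.append(comp * age)
        names.append("comp:age")
    if form == "comp_x_age_x_group":
        levels = sorted(map(str, d[group_col].astype(str).unique()))
        if len(levels) != 2:
            raise ValueError("three-way form requires exactly two groups")
        g = (d[group_col].astype(str) == levels[1]).to_numpy(dtype=float)
        cols += [g, comp * g, age * g, comp * age * g]
        names += ["group", "comp:group", "age:group", "comp:age:group"]
    X = np.column_stack(cols + ([S] if S.shape[1] else []))
    names = names + site_names
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[i] for i in np.flatnonzero(np.abs(np.diag(R)) < 1e-8)]
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    res = sm.OLS(y, X).fit()
    headline = {"comp": "comp", "comp_x_age": "comp:age", "comp_x_age_x_group": "comp:age:group"}[form]
    i = names.index(headline)
    terms = {
        nm: (float(res.params[j]), float(res.tvalues[j]), float(res.pvalues[j]))
        for j, nm in enumerate(names)
    }
    return PredictionResult(
        outcome=outcome_name,
        form=form,
        headline_term=headline,
        std_beta=float(res.params[i]),
        t_stat=float(res.tvalues[i]),
        p_value=float(res.pvalues[i]),
        p_adjusted=None,
        n=len(d),
        terms=terms,
    )
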