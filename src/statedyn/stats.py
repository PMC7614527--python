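"""Cross-sectional group inference for brain-state dynamics metrics.

Contains:

* a random-intercept linear mixed model (REML, one grouping factor — scan
  site) with Satterthwaite-approximated denominator degrees of freedom for
  Wald F tests, plus a fixed-effects ANCOVA fallback when only one site is
  present;
* model comparison between linear and quadratic age trends using
  orthogonalized polynomials (ML likelihood-ratio test and AIC);
* group-by-age interaction contrasts;
* a max-statistic permutation test for group differences in the K x K
  transition/persistence probability matrices, with age and sex as nuisance
  covariates and family-wise error control across all cells and both
  contrast directions;
* Benjamini-Hochberg FDR adjustment;
* the converter-versus-non-converter contrast at the latest presymptomatic
  scan.

The mixed model is implemented directly (profiled REML over the
variance-ratio parameter with closed-form block inverses) so that the
Satterthwaite degrees of freedom are available; it is cross-checked against
lme4/lmerTest in the test suite.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from . import qc as _qc

__all__ = [
    "ContrastResult",
    "PermutationResult",
    "LmmFit",
    "fit_lmm",
    "fit_metric_model",
    "orthogonal_polynomials",
    "compare_age_models",
    "group_by_age_interaction",
    "permutation_test_transitions",
    "fdr_adjust",
    "converter_contrast",
]


# --------------------------------------------------------------------------
# random-intercept LMM with Satterthwaite df
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LmmFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    loglik: float  # REML or ML criterion at the optimum (with constants)
    reml: bool
    n: int
    p: int
    columns: tuple[str, ...]
    group_sizes: np.ndarray
    group_codes: np.ndarray
    X: np.ndarray
    y: np.ndarray

    @property
    def aic(self) -> float:
        k = self.p + 2  # fixed effects + two variance parameters
        return -2.0 * self.loglik + 2.0 * k

    @property
    def residual_df(self) -> int:
        return self.n - self.p


def _w_apply(v: np.ndarray, codes: np.ndarray, sizes: np.ndarray, lam: float) -> np.ndarray:
    """(I + lam * Z Z^T)^{-1} v with Z the site indicator matrix (block form)."""
    if lam == 0.0:
        return v
    out = v.astype(float).copy()
    shrink = lam / (1.0 + lam * sizes)
    if v.ndim == 1:
        sums = np.bincount(codes, weights=v, minlength=len(sizes))
        out -= (shrink * sums)[codes]
    else:
        for j in range(v.shape[1]):
            sums = np.bincount(codes, weights=v[:, j], minlength=len(sizes))
            out[:, j] -= (shrink * sums)[codes]
    return out


def _profiled_crit(lam, y, X, codes, sizes, reml):
    """Profiled (over beta, sigma2) log-likelihood at variance ratio lam."""
    n, p = X.shape
    Wy = _w_apply(y, codes, sizes, lam)
    WX = _w_apply(X, codes, sizes, lam)
    XtWX = X.T @ WX
    beta = np.linalg.solve(XtWX, X.T @ Wy)
    r = y - X @ beta
    rWr = float(r @ _w_apply(r, codes, sizes, lam))
    logdet_blocks = float(np.log1p(lam * sizes).sum())
    if reml:
        sigma2 = rWr / (n - p)
        sign, logdet_x = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            (n - p) * math.log(sigma2)
            + logdet_blocks
            + logdet_x
            + (n - p)
            + (n - p) * math.log(2.0 * math.pi)
        )
    else:
        sigma2 = rWr / n
        ll = -0.5 * (n * math.log(sigma2) + logdet_blocks + n + n * math.log(2.0 * math.pi))
    return ll, beta, sigma2, XtWX


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    site: np.ndarray | None,
    *,
    reml: bool = True,
    columns: tuple[str, ...] | None = None,
) -> LmmFit:
    """Fit ``y = X beta + site intercept + noise`` by (RE)ML.

    The single variance-ratio parameter ``lam = tau^2 / sigma^2`` is profiled
    and optimized on a deterministic log grid refined by bounded search;
    ``lam = 0`` (no site variance) is always a candidate, so the model
    degrades gracefully to OLS.  ``site=None`` forces the fixed-effects
    model.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if columns is None:
        columns = tuple(f"x{j}" for j in range(p))
    if site is None:
        codes = np.zeros(n, dtype=int)
        sizes = np.array([n], dtype=float)
        lam_hat = 0.0
    else:
        _, codes = np.unique(np.asarray(site), return_inverse=True)
        sizes = np.bincount(codes).astype(float)
        if len(sizes) < 2:
            lam_hat = 0.0
        else:
            grid = np.concatenate([[0.0], 10.0 ** np.linspace(-6, 3, 37)])
            vals = [_profiled_crit(l, y, X, codes, sizes, reml)[0] for l in grid]
            i = int(np.argmax(vals))
            lam_hat = grid[i]
            if 0 < i < len(grid) - 1:
                res = optimize.minimize_scalar(
                    lambda l: -_profiled_crit(l, y, X, codes, sizes, reml)[0],
                    bounds=(grid[i - 1], grid[i + 1]),
                    method="bounded",
                    options={"xatol": 1e-10},
                )
                if -res.fun > vals[i]:
                    lam_hat = float(res.x)
    ll, beta, sigma2, XtWX = _profiled_crit(lam_hat, y, X, codes, sizes, reml)
    cov_beta = sigma2 * np.linalg.inv(XtWX)
    return LmmFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        tau2=float(lam_hat * sigma2),
        loglik=float(ll),
        reml=reml,
        n=n,
        p=p,
        columns=columns,
        group_sizes=sizes,
        group_codes=codes,
        X=X,
        y=y,
    )


def _reml_theta(theta, fit: LmmFit) -> float:
    """Unprofiled REML criterion as a function of (sigma2, tau2) >= 0."""
    sigma2, tau2 = float(theta[0]), float(theta[1])
    lam = tau2 / sigma2
    y, X, codes, sizes = fit.y, fit.X, fit.group_codes, fit.group_sizes
    n, p = X.shape
    Wy = _w_apply(y, codes, sizes, lam)
    WX = _w_apply(X, codes, sizes, lam)
    XtWX = X.T @ WX
    beta = np.linalg.solve(XtWX, X.T @ Wy)
    r = y - X @ beta
    quad = float(r @ _w_apply(r, codes, sizes, lam)) / sigma2
    logdet_v = n * math.log(sigma2) + float(np.log1p(lam * sizes).sum())
    _, logdet_x = np.linalg.slogdet(XtWX / sigma2)
    return -0.5 * (logdet_v + logdet_x + quad)


def _cov_contrast(theta, fit: LmmFit, L: np.ndarray) -> np.ndarray:
    """L C(theta) L^T with C(theta) = (X^T V(theta)^{-1} X)^{-1}."""
    sigma2, tau2 = float(theta[0]), float(theta[1])
    lam = tau2 / sigma2
    WX = _w_apply(fit.X, fit.group_codes, fit.group_sizes, lam)
    C = sigma2 * np.linalg.inv(fit.X.T @ WX)
    return L @ C @ L.T


def _satterthwaite_f(fit: LmmFit, L: np.ndarray) -> tuple[float, float, float]:
    """Wald F for contrast L with Satterthwaite denominator df.

    Follows the eigendecomposition approach used by lmerTest: the F statistic
    is split into q independent t^2 components, each gets a Satterthwaite df
    from the delta method with the numerical REML information matrix, and the
    component dfs are pooled.  Returns (F, df2, p).
    """
    L = np.atleast_2d(L)
    q = L.shape[0]
    theta = np.array([fit.sigma2, fit.tau2])
    M = _cov_contrast(theta, fit, L)
    Minv = np.linalg.inv(M)
    F = float(fit.beta @ L.T @ Minv @ L @ fit.beta) / q

    if fit.tau2 <= 1e-10 * fit.sigma2 or len(fit.group_sizes) < 2:
        df2 = float(fit.residual_df)
        return F, df2, float(sps.f.sf(F, q, df2))

    # observed information of the REML criterion in (sigma2, tau2)
    h = np.maximum(theta * 1e-4, 1e-10)
    H = np.zeros((2, 2))
    f0 = _reml_theta(theta, fit)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            if i == j:
                f1 = _reml_theta(theta + ei, fit)
                f2 = _reml_theta(theta - ei, fit)
                H[i, i] = (f1 - 2 * f0 + f2) / h[i] ** 2
            else:
                fpp = _reml_theta(theta + ei + ej, fit)
                fpm = _reml_theta(theta + ei - ej, fit)
                fmp = _reml_theta(theta - ei + ej, fit)
                fmm = _reml_theta(theta - ei - ej, fit)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return F, float(fit.residual_df), float(sps.f.sf(F, q, fit.residual_df))
    if np.any(np.diag(A) <= 0):
        return F, float(fit.residual_df), float(sps.f.sf(F, q, fit.residual_df))

    w, U = np.linalg.eigh(M)
    dfs = []
    for i in range(q):
        li = U[:, i] @ L  # contrast in beta space
        Li = li[None, :]
        var_i = float(_cov_contrast(theta, fit, Li)[0, 0])
        g = np.zeros(2)
        for j in range(2):
            ej = np.eye(2)[j] * h[j]
            g[j] = (
                float(_cov_contrast(theta + ej, fit, Li)[0, 0])
                - float(_cov_contrast(theta - ej, fit, Li)[0, 0])
            ) / (2 * h[j])
        denom = float(g @ A @ g)
        nu = 2.0 * var_i**2 / denom if denom > 0 else float(fit.residual_df)
        dfs.append(max(nu, 1.01))
    dfs = np.asarray(dfs)
    good = dfs > 2.0
    if not np.any(good):
        df2 = float(fit.residual_df)
    else:
        E = float(np.sum(dfs[good] / (dfs[good] - 2.0)))
        df2 = 2.0 * E / (E - np.sum(good)) if E > np.sum(good) else float(fit.residual_df)
    return F, df2, float(sps.f.sf(F, q, df2))


# --------------------------------------------------------------------------
# design helpers
# --------------------------------------------------------------------------


def _encode_sex(s: pd.Series) -> np.ndarray:
    if s.dtype.kind in "ifb":
        return s.to_numpy(dtype=float)
    return s.astype(str).str.upper().map({"F": 0.0, "M": 1.0}).to_numpy(dtype=float)


def _group_dummies(g: pd.Series) -> tuple[np.ndarray, list[str], list[str]]:
    levels = sorted(map(str, g.astype(str).unique()))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    cols = []
    names = []
    gs = g.astype(str)
    for lev in levels[1:]:
        cols.append((gs == lev).to_numpy(dtype=float))
        names.append(f"group[{lev}]")
    return np.column_stack(cols), names, levels


def orthogonal_polynomials(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis columns 1..degree (orthogonal to intercept)."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        raise ValueError("age variance must be positive")
    V = np.vander(x, degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    Q = Q[:, 1 : degree + 1]
    # fix signs: leading coefficient positive (increasing polynomial)
    for j in range(Q.shape[1]):
        if np.polyfit(x, Q[:, j], j + 1)[0] < 0:
            Q[:, j] = -Q[:, j]
    return Q


@dataclass(frozen=True)
class ContrastResult:
    """One tested effect: Wald F with (Satterthwaite) dfs, p values, effect size."""

    effect: str
    f_stat: float
    df_num: float
    df_den: float
    p_value: float
    p_adjusted: float | None = None
    effect_size: float = float("nan")  # partial eta squared
    estimate: float = float("nan")  # signed estimate for 1-df contrasts
    note: str = ""

    def adjusted(self, p_adj: float) -> "ContrastResult":
        return ContrastResult(
            **{**self.__dict__, "p_adjusted": float(max(p_adj, self.p_value))}
        )


def fit_metric_model(
    df: pd.DataFrame,
    value_col: str,
    *,
    group_col: str = "group",
    covariate_cols: tuple[str, ...] = ("age", "sex"),
    site_col: str | None = "site",
    random_intercept: bool = True,
    effect_name: str | None = None,
) -> ContrastResult:
    """Group contrast on one dynamics metric, adjusting for age and sex.

    With two or more scan sites and ``random_intercept=True`` the model is a
    linear mixed model with a site random intercept and the group F test uses
    Satterthwaite denominator degrees of freedom.  With a single site (or
    ``random_intercept=False``) it is a one-way ANCOVA.  Returns the group
    main-effect contrast; for two groups the signed estimate (second level
    minus first, adjusted) is attached.
    """
    d = df.dropna(subset=[value_col]).reset_index(drop=True)
    y = d[value_col].to_numpy(dtype=float)
    G, gnames, levels = _group_dummies(d[group_col])
    covs = []
    cov_names = []
    for c in covariate_cols:
        covs.append(_encode_sex(d[c]) if c == "sex" else d[c].to_numpy(dtype=float))
        cov_names.append(c)
    X = np.column_stack([np.ones(len(d)), G] + covs)
    columns = tuple(["intercept"] + gnames + cov_names)
    site = None
    note = ""
    if random_intercept and site_col is not None and site_col in d.columns:
        if d[site_col].nunique() >= 2:
            site = d[site_col].to_numpy()
        else:
            note = "single site: fell back to fixed-effects ANCOVA"
            warnings.warn(note, stacklevel=2)
    fit = fit_lmm(y, X, site, reml=True, columns=columns)
    q = G.shape[1]
    L = np.zeros((q, X.shape[1]))
    for i in range(q):
        L[i, 1 + i] = 1.0
    F, df2, p = _satterthwaite_f(fit, L)
    est = float(fit.beta[1]) if q == 1 else float("nan")
    return ContrastResult(
        effect=effect_name or f"{value_col}~{group_col}",
        f_stat=F,
        df_num=float(q),
        df_den=df2,
        p_value=p,
        effect_size=q * F / (q * F + df2),
        estimate=est,
        note=note,
    )


def compare_age_models(
    df: pd.DataFrame,
    value_col: str,
    *,
    age_col: str = "age",
    sex_col: str = "sex",
    site_col: str | None = "site",
    degree: int = 2,
) -> dict:
    """Likelihood-ratio / AIC comparison of linear vs quadratic age trends.

    Both models carry sex as a covariate and (when available) a site random
    intercept; they are fit by maximum likelihood so the LRT is valid.  The
    age basis uses orthogonalized polynomials, so the quadratic column is
    orthogonal to the linear one.
    """
    if degree != 2:
        raise ValueError("comparison is linear (1) vs quadratic (2); degree must be 2")
    d = df.dropna(subset=[value_col]).reset_index(drop=True)
    y = d[value_col].to_numpy(dtype=float)
    P = orthogonal_polynomials(d[age_col].to_numpy(dtype=float), 2)
    sex = _encode_sex(d[sex_col])
    site = (
        d[site_col].to_numpy()
        if site_col is not None and site_col in d.columns and d[site_col].nunique() >= 2
        else None
    )
    X1 = np.column_stack([np.ones(len(d)), sex, P[:, :1]])
    X2 = np.column_stack([np.ones(len(d)), sex, P])
    f1 = fit_lmm(y, X1, site, reml=False)
    f2 = fit_lmm(y, X2, site, reml=False)
    lrt = max(0.0, 2.0 * (f2.loglik - f1.loglik))
    p = float(sps.chi2.sf(lrt, df=1))
    return {
        "value": value_col,
        "lrt_stat": lrt,
        "lrt_df": 1,
        "lrt_p": p,
        "aic_linear": f1.aic,
        "aic_quadratic": f2.aic,
        "quadratic_preferred": (p < 0.05) and (f2.aic < f1.aic),
    }


def group_by_age_interaction(
    df: pd.DataFrame,
    value_col: str,
    *,
    group_col: str = "group",
    age_col: str = "age",
    sex_col: str = "sex",
    site_col: str | None = "site",
    degree: int = 1,
    random_intercept: bool = True,
) -> ContrastResult:
    """F test of the group-by-age interaction (age linear or quadratic)."""
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    d = df.dropna(subset=[value_col]).reset_index(drop=True)
    y = d[value_col].to_numpy(dtype=float)
    G, gnames, _ = _group_dummies(d[group_col])
    P = orthogonal_polynomials(d[age_col].to_numpy(dtype=float), degree)
    sex = _encode_sex(d[sex_col])
    inter = np.column_stack(
        [G[:, i] * P[:, j] for i in range(G.shape[1]) for j in range(degree)]
    )
    X = np.column_stack([np.ones(len(d)), sex, G, P, inter])
    site = (
        d[site_col].to_numpy()
        if random_intercept
        and site_col is not None
        and site_col in d.columns
        and d[site_col].nunique() >= 2
        else None
    )
    fit = fit_lmm(y, X, site, reml=True)
    q = inter.shape[1]
    L = np.zeros((q, X.shape[1]))
    for i in range(q):
        L[i, X.shape[1] - q + i] = 1.0
    F, df2, p = _satterthwaite_f(fit, L)
    return ContrastResult(
        effect=f"{value_col}~{group_col}:age^{degree}",
        f_stat=F,
        df_num=float(q),
        df_den=df2,
        p_value=p,
        effect_size=q * F / (q * F + df2),
    )


# --------------------------------------------------------------------------
# permutation test on transition matrices
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationResult:
    t_obs: np.ndarray  # K x K observed group t statistics
    p_fwe: np.ndarray  # K x K family-wise-error-corrected p values
    n_perm: int
    seed: int | None
    exact: bool

    def significant(self, level: float = 0.05) -> np.ndarray:
        return self.p_fwe <= level


def _perm_tstats(Ey: np.ndarray, gR: np.ndarray, ss_y: np.ndarray, df: int) -> np.ndarray:
    """t statistics for all cells given a residualized (permuted) group vector."""
    ss_g = float(gR @ gR)
    u = gR @ Ey  # per-cell cross products
    resid = np.maximum(ss_y - u**2 / ss_g, 1e-300)
    return u / np.sqrt(ss_g) / np.sqrt(resid / df)


def permutation_test_transitions(
    matrices: np.ndarray,
    labels: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None,
    n_perm: int = 5000,
    seed: int = 0,
) -> PermutationResult:
    """Max-statistic permutation test on per-subject transition matrices.

    The K*K transition/persistence probabilities are interdependent, so each
    cell's two-group contrast (with age and sex residualized out of both the
    metric and the permuted group indicator) is referred to the permutation
    distribution of the maximum |t| over ALL cells — family-wise error
    control across every cell and both contrast directions.  P values use the
    (1 + #{exceedances}) / (n_perm + 1) convention, so no p can be zero.
    When the number of distinct group-label splits is at most ``n_perm`` the
    full set is enumerated and the p values are exact.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    M = np.asarray(matrices, dtype=float)
    if M.ndim != 3 or M.shape[1] != M.shape[2]:
        raise ValueError("matrices must be N x K x K")
    n, K, _ = M.shape
    Y = M.reshape(n, K * K)
    lab = np.asarray(labels)
    levs = np.unique(lab)
    if len(levs) != 2:
        raise ValueError("permutation test requires exactly two groups")
    g = (lab == levs[1]).astype(float)
    n1 = int(g.sum())
    if covariates is None:
        Z = np.ones((n, 1))
    else:
        Cv = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.atleast_2d(np.asarray(covariates, dtype=float))
        )
        if Cv.shape[0] != n:
            Cv = Cv.T
        Z = np.column_stack([np.ones(n), Cv])
    Qz, _ = np.linalg.qr(Z)
    Ey = Y - Qz @ (Qz.T @ Y)
    ss_y = np.einsum("ij,ij->j", Ey, Ey)
    df = n - Z.shape[1] - 1

    def resid_g(gv: np.ndarray) -> np.ndarray:
        return gv - Qz @ (Qz.T @ gv)

    t_obs = _perm_tstats(Ey, resid_g(g), ss_y, df)

    total_splits = math.comb(n, n1)
    exact = total_splits <= n_perm
    if exact:
        maxima = np.empty(total_splits)
        for i, ones in enumerate(itertools.combinations(range(n), n1)):
            gp = np.zeros(n)
            gp[list(ones)] = 1.0
            maxima[i] = np.abs(_perm_tstats(Ey, resid_g(gp), ss_y, df)).max()
        p = (maxima[:, None] >= np.abs(t_obs)[None, :] - 1e-12).mean(axis=0)
        n_used = total_splits
    else:
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_perm)
        for i in range(n_perm):
            gp = rng.permutation(g)
            maxima[i] = np.abs(_perm_tstats(Ey, resid_g(gp), ss_y, df)).max()
        exceed = (maxima[:, None] >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
        p = (1.0 + exceed) / (n_perm + 1.0)
        n_used = n_perm
    return PermutationResult(
        t_obs=t_obs.reshape(K, K),
        p_fwe=p.reshape(K, K),
        n_perm=n_used,
        seed=seed,
        exact=exact,
    )


# --------------------------------------------------------------------------
# FDR
# --------------------------------------------------------------------------


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p values must be a 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


# --------------------------------------------------------------------------
# converters
# --------------------------------------------------------------------------


def converter_contrast(
    scans: pd.DataFrame,
    value_col: str,
    *,
    converter_col: str = "converter",
    group_col: str = "group",
    presymptomatic_label: str = "presymptomatic",
    covariate_cols: tuple[str, ...] = ("age", "sex"),
    site_col: str | None = "site",
) -> ContrastResult:
    """Converters vs non-converting carriers at the latest presymptomatic scan.

    Scans are restricted to the presymptomatic phase (converters' symptomatic
    scans, if any, are ignored), the latest QC-passing scan per subject is
    selected, and the converter flag is tested as the group main effect in
    the mixed metric model.  The signed estimate is converter minus
    non-converter.
    """
    pre = scans[scans[group_col].astype(str) == presymptomatic_label]
    if pre.empty:
        raise ValueError("no presymptomatic scans")
    latest = _qc.select_scan(pre, "latest")
    if latest[converter_col].astype(bool).sum() < 2:
        raise ValueError("need at least 2 converters")
    d = latest.copy()
    d["_conv"] = d[converter_col].astype(bool).map({False: "a_nonconverter", True: "b_converter"})
    return fit_metric_model(
        d,
        value_col,
        group_col="_conv",
        covariate_cols=covariate_cols,
        site_col=site_col,
        effect_name=f"{value_col}~converter",
    )
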