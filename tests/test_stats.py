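"""Group inference: mixed models, age models, permutation test, FDR."""
import itertools
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from statedyn.stats import (
    compare_age_models,
    converter_contrast,
    fdr_adjust,
    fit_lmm,
    fit_metric_model,
    group_by_age_interaction,
    orthogonal_polynomials,
    permutation_test_transitions,
)


def _cohort_frame(rng, n_per_group=30, n_sites=3, shift=0.0, site_sd=0.0):
    n = n_per_group * 2
    group = np.repeat(["noncarrier", "symptomatic"], n_per_group)
    site = rng.integers(0, n_sites, size=n)
    age = rng.normal(55, 10, size=n)
    sex = rng.integers(0, 2, size=n)
    site_eff = rng.normal(0, site_sd, size=n_sites)
    y = rng.normal(0, 1, size=n) + shift * (group == "symptomatic") + site_eff[site]
    return pd.DataFrame(
        {"value": y, "group": group, "age": age, "sex": sex, "site": [f"s{i}" for i in site]}
    )


class TestMixedModel:
    def test_against_lmerTest_oracle(self):
        """F statistic and Satterthwaite df match lme4/lmerTest on a fixture."""
        rng = np.random.default_rng(7)
        df = _cohort_frame(rng, n_per_group=40, n_sites=5, shift=0.6, site_sd=0.8)
        res = fit_metric_model(df, "value")
        with tempfile.TemporaryDirectory() as td:
            csv = Path(td) / "d.csv"
            df.to_csv(csv, index=False)
            rcode = (
                "suppressMessages(library(lmerTest));"
                f"d <- read.csv('{csv}');"
                "m <- lmer(value ~ group + age + sex + (1|site), data=d);"
                "a <- anova(m, ddf='Satterthwaite');"
                "cat(a['group','F value'], a['group','DenDF'], a['group','Pr(>F)'])"
            )
            out = subprocess.run(
                ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
            )
        f_r, df_r, p_r = map(float, out.stdout.split())
        assert res.f_stat == pytest.approx(f_r, rel=1e-3)
        assert res.df_den == pytest.approx(df_r, rel=0.05)
        assert res.p_value == pytest.approx(p_r, rel=0.01, abs=1e-6)

    def test_zero_variance_site_matches_ancova(self):
        # seed chosen so the REML site-variance estimate hits the zero boundary
        rng = np.random.default_rng(0)
        df = _cohort_frame(rng, n_per_group=25, n_sites=3, shift=0.5, site_sd=0.0)
        mixed = fit_metric_model(df, "value", random_intercept=True)
        fixed = fit_metric_model(df, "value", random_intercept=False)
        assert mixed.f_stat == pytest.approx(fixed.f_stat, abs=1e-6)
        assert mixed.df_den == fixed.df_den

    def test_single_site_falls_back_with_warning(self):
        rng = np.random.default_rng(3)
        df = _cohort_frame(rng, n_per_group=20, n_sites=1)
        with pytest.warns(UserWarning, match="single site"):
            res = fit_metric_model(df, "value")
        assert res.df_den == pytest.approx(len(df) - 4)

    def test_null_calibration(self):
        """Type-I error of the group test is nominal under the null."""
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(10_000 + rep)
            df = _cohort_frame(rng, n_per_group=25, n_sites=3, site_sd=0.5)
            pvals.append(fit_metric_model(df, "value").p_value)
        pvals = np.asarray(pvals)
        rej = (pvals < 0.05).sum()
        assert 3 <= rej <= 18  # binomial 99% band around 10/200
        assert sps.kstest(pvals, "uniform").pvalue > 0.005

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        df = _cohort_frame(rng, n_per_group=50, n_sites=3, shift=1.0, site_sd=0.3)
        res = fit_metric_model(df, "value")
        assert res.p_value < 0.01
        assert res.estimate > 0
        assert 0 <= res.effect_size <= 1


class TestAgeModels:
    def test_orthogonal_polynomial_columns(self, rng):
        P = orthogonal_polynomials(rng.normal(50, 10, size=80), 2)
        assert abs(P[:, 0] @ P[:, 1]) < 1e-10
        assert abs(P[:, 0].sum()) < 1e-10 and abs(P[:, 1].sum()) < 1e-10

    def test_quadratic_favored_under_u_shape(self):
        wins = 0
        for rep in range(15):
            rng = np.random.default_rng(300 + rep)
            age = rng.uniform(30, 80, size=150)
            y = 0.002 * (age - 55) ** 2 + rng.normal(0, 0.3, size=150)
            df = pd.DataFrame(
                {"value": y, "age": age, "sex": rng.integers(0, 2, 150), "site": "s1"}
            )
            rec = compare_age_models(df, "value")
            wins += rec["lrt_p"] < 0.05 and rec["aic_quadratic"] < rec["aic_linear"]
        assert wins >= 13

    def test_quadratic_not_favored_under_linear_trend(self):
        wins = 0
        for rep in range(40):
            rng = np.random.default_rng(600 + rep)
            age = rng.uniform(30, 80, size=150)
            y = 0.02 * age + rng.normal(0, 0.5, size=150)
            df = pd.DataFrame(
                {"value": y, "age": age, "sex": rng.integers(0, 2, 150), "site": "s1"}
            )
            wins += compare_age_models(df, "value")["lrt_p"] < 0.05
        assert wins <= 7  # 99.9% binomial bound at the nominal 5% level

    def test_group_age_interaction_detected_and_destroyed(self):
        rng = np.random.default_rng(41)
        n = 200
        group = np.repeat(["noncarrier", "presymptomatic"], n // 2)
        age = rng.uniform(30, 80, size=n)
        y = rng.normal(0, 0.5, size=n) + np.where(
            (group == "presymptomatic") & (age > 55), 0.02 * (age - 55), 0.0
        )
        df = pd.DataFrame(
            {"value": y, "group": group, "age": age, "sex": rng.integers(0, 2, n), "site": "s1"}
        )
        hit = group_by_age_interaction(df, "value", degree=2)
        assert hit.p_value < 0.05
        df_null = df.copy()
        df_null["group"] = rng.permutation(group)
        miss = group_by_age_interaction(df_null, "value", degree=2)
        assert miss.p_value > 0.05


class TestPermutationTest:
    @staticmethod
    def _small_data(rng, n=8, K=2):
        mats = rng.dirichlet(np.ones(K) * 5, size=(n, K))
        labels = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        cov = pd.DataFrame(
            {"age": rng.normal(50, 8, n), "sex": rng.integers(0, 2, n).astype(float)}
        )
        return mats, labels, cov

    def test_exact_enumeration_matches_brute_force(self, rng):
        """p values at n=8 equal the exact distribution over all 70 label splits."""
        import statsmodels.api as sm

        mats, labels, cov = self._small_data(rng)
        res = permutation_test_transitions(mats, labels, cov, n_perm=500, seed=0)
        assert res.exact and res.n_perm == 70

        Y = mats.reshape(8, -1)
        Z = np.column_stack([np.ones(8), cov.to_numpy()])

        def cell_ts(g):
            ts = []
            for j in range(Y.shape[1]):
                X = np.column_stack([Z, g])
                fit = sm.OLS(Y[:, j], X).fit()
                ts.append(fit.tvalues[-1])
            return np.asarray(ts)

        t_obs = cell_ts((labels == "b").astype(float))
        assert np.allclose(res.t_obs.ravel(), t_obs, atol=1e-10)
        maxima = []
        for ones in itertools.combinations(range(8), 4):
            g = np.zeros(8)
            g[list(ones)] = 1.0
            maxima.append(np.abs(cell_ts(g)).max())
        maxima = np.asarray(maxima)
        p_brute = (maxima[:, None] >= np.abs(t_obs)[None, :] - 1e-12).mean(axis=0)
        assert np.allclose(res.p_fwe.ravel(), p_brute, atol=1e-12)

    def test_state_relabel_invariance(self, rng):
        mats = rng.dirichlet(np.ones(3) * 5, size=(24, 3))
        labels = np.array(["a", "b"] * 12)
        cov = pd.DataFrame({"age": rng.normal(50, 8, 24)})
        res = permutation_test_transitions(mats, labels, cov, n_perm=300, seed=4)
        perm = np.array([2, 0, 1])
        res_p = permutation_test_transitions(
            mats[:, perm][:, :, perm], labels, cov, n_perm=300, seed=4
        )
        assert np.allclose(res_p.p_fwe, res.p_fwe[np.ix_(perm, perm)], atol=1e-12)

    def test_planted_cell_detected(self, rng):
        n = 60
        mats = rng.dirichlet(np.ones(3) * 30, size=(n, 3))
        labels = np.array(["a"] * 30 + ["b"] * 30)
        bump = np.zeros((3, 3))
        bump[1, 1] = 0.12
        mats[30:] = mats[30:] * (1 - 0.12) + bump  # renormalized persistence bump
        cov = pd.DataFrame({"age": rng.normal(50, 8, n), "sex": rng.integers(0, 2, n)})
        res = permutation_test_transitions(mats, labels, cov, n_perm=500, seed=1)
        assert res.p_fwe[1, 1] < 0.05
        assert res.p_fwe.min() >= 1.0 / (res.n_perm + 1)

    def test_requires_two_groups_and_enough_perms(self, rng):
        mats, labels, cov = self._small_data(rng)
        with pytest.raises(ValueError):
            permutation_test_transitions(mats, np.repeat("a", 8), cov, n_perm=500)
        with pytest.raises(ValueError):
            permutation_test_transitions(mats, labels, cov, n_perm=50)


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        adj = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            mine = fdr_adjust(p)
            _, theirs, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(mine, theirs, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_adjusted_geq_raw_and_order_preserving(self, p):
        p = np.asarray(p)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestConverterContrast:
    @staticmethod
    def _scans(rng, effect=0.0, n_conv=6, n_non=40):
        rows = []
        for i in range(n_conv + n_non):
            conv = i < n_conv
            for visit in range(2):
                rows.append(
                    {
                        "subject_id": f"p{i}",
                        "scan_id": f"p{i}_v{visit}",
                        "group": "presymptomatic",
                        "converter": conv,
                        "visit_index": visit,
                        "n_volumes": 200,
                        "qc_pass": True,
                        "age": float(rng.normal(50, 8)),
                        "sex": int(rng.integers(0, 2)),
                        "site": f"s{int(rng.integers(0, 3))}",
                        # only the LATEST presymptomatic scan carries the effect
                        "value": float(rng.normal(0, 1) + (effect if conv and visit == 1 else 0)),
                    }
                )
        return pd.DataFrame(rows)

    def test_planted_converter_effect_recovered(self, rng):
        df = self._scans(rng, effect=2.0)
        res = converter_contrast(df, "value")
        assert res.estimate > 0
        assert res.p_value < 0.05

    def test_null_converter_effect(self):
        rng = np.random.default_rng(19)
        df = self._scans(rng, effect=0.0)
        res = converter_contrast(df, "value")
        assert res.p_value > 0.01

    def test_requires_two_converters(self, rng):
        df = self._scans(rng, n_conv=1)
        with pytest.raises(ValueError, match="converters"):
            converter_contrast(df, "value")


def test_fit_lmm_recovers_variance_components():
    rng = np.random.default_rng(8)
    n_sites, per = 10, 30
    site = np.repeat(np.arange(n_sites), per)
    eff = rng.normal(0, 1.0, n_sites)
    X = np.column_stack([np.ones(n_sites * per), rng.normal(size=n_sites * per)])
    y = X @ np.array([1.0, 0.5]) + eff[site] + rng.normal(0, 0.7, n_sites * per)
    fit = fit_lmm(y, X, site)
    assert fit.tau2 == pytest.approx(1.0, abs=0.6)
    assert fit.sigma2 == pytest.approx(0.49, abs=0.1)
    assert fit.beta[1] == pytest.approx(0.5, abs=0.1)
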