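"""Two-step longitudinal prediction: floors, slope estimation, stage two."""
import numpy as np
import pandas as pd
import pytest

from statedyn.longitudinal import (
    FloorDefinition,
    encode_site,
    estimate_slopes,
    predict_decline,
    remove_floor,
)


def _visits(slopes, intercepts, n_visits=6, noise=0.0, rng=None, outcome="cognition"):
    rows = []
    for i, (b, a) in enumerate(zip(slopes, intercepts)):
        for t in range(n_visits):
            eps = 0.0 if rng is None else float(rng.normal(0, noise))
            rows.append(
                {"subject_id": f"s{i:03d}", "years_from_baseline": float(t), outcome: a + b * t + eps}
            )
    return pd.DataFrame(rows)


class TestRemoveFloor:
    def test_identity_when_no_floor_hit(self):
        v = _visits([0.5, -0.5], [20.0, 25.0])
        out, report = remove_floor(v, {"cognition": FloorDefinition(floor=0.0)})
        assert out["cognition"].equals(v)
        assert report.iloc[0]["n_removed"] == 0

    def test_three_of_ten_at_floor(self):
        intercepts = [0.0, 0.0, 0.0] + [20.0] * 7
        v = _visits([0.1] * 10, intercepts)
        out, report = remove_floor(v, {"cognition": FloorDefinition(floor=0.0)})
        kept = set(out["cognition"]["subject_id"])
        assert len(kept) == 7
        assert {"s000", "s001", "s002"}.isdisjoint(kept)
        assert report.iloc[0]["n_removed"] == 3

    def test_removal_is_outcome_local(self):
        v = _visits([0.1] * 4, [0.0, 20.0, 20.0, 20.0], outcome="mmse_like")
        timed = _visits([1.0] * 4, [300.0, 100.0, 100.0, 100.0], outcome="tmt_like")
        merged = v.merge(timed, on=["subject_id", "years_from_baseline"])
        out, _ = remove_floor(
            merged,
            {
                "mmse_like": FloorDefinition(floor=0.0),
                "tmt_like": FloorDefinition(ceiling=300.0),
            },
        )
        assert "s000" not in set(out["mmse_like"]["subject_id"])  # floored on mmse
        assert "s000" not in set(out["tmt_like"]["subject_id"])  # at ceiling on tmt
        assert "s001" in set(out["mmse_like"]["subject_id"])
        assert set(out["tmt_like"]["subject_id"]) == {"s001", "s002", "s003"}

    def test_unknown_outcome(self):
        v = _visits([0.1], [10.0])
        with pytest.raises(ValueError, match="unknown outcome"):
            remove_floor(v, {"nope": FloorDefinition(floor=0.0)})


class TestEstimateSlopes:
    def test_noise_free_recovery(self):
        true_slopes = np.linspace(-2.0, 1.0, 15)
        v = _visits(true_slopes, np.full(15, 20.0), n_visits=6)
        slopes = estimate_slopes(v, "cognition")
        err = np.abs(slopes.sort_values("subject_id")["slope"].to_numpy() - true_slopes)
        assert err.max() < 0.05

    def test_single_visit_shrunk_to_population(self):
        rng = np.random.default_rng(4)
        v = _visits(
            rng.normal(-1.0, 0.5, 20), rng.normal(20.0, 2.0, 20), n_visits=5, noise=0.5, rng=rng
        )
        lone = pd.DataFrame(
            {"subject_id": ["lonely"], "years_from_baseline": [0.0], "cognition": [21.0]}
        )
        slopes = estimate_slopes(pd.concat([v, lone], ignore_index=True), "cognition")
        fixed = slopes.attrs["fixed_slope"]
        lone_dev = abs(
            slopes.set_index("subject_id").loc["lonely", "slope"] - fixed
        )
        multi_dev = (
            (slopes[slopes["subject_id"] != "lonely"]["slope"] - fixed).abs().max()
        )
        assert lone_dev < multi_dev
        assert slopes.set_index("subject_id").loc["lonely", "n_visits"] == 1

    def test_population_slope_recovered(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(50 + rep)
            true = rng.normal(-1.5, 0.4, 40)
            v = _visits(true, np.full(40, 25.0), n_visits=4, noise=1.0, rng=rng)
            slopes = estimate_slopes(v, "cognition")
            est = slopes.attrs["fixed_slope"]
            # population slope ~ N(-1.5, 0.4/sqrt(40)) plus estimation noise
            hits += abs(est - true.mean()) < 0.15
        assert hits >= 9

    def test_all_single_visit_rejected(self):
        v = _visits([0.1, 0.2], [10.0, 12.0], n_visits=1)
        with pytest.raises(ValueError):
            estimate_slopes(v, "cognition")


class TestPredictDecline:
    @staticmethod
    def _frame(rng, n=80, link=0.0, site_conf=0.0, two_groups=False):
        comp = rng.normal(0, 1, n)
        site = rng.integers(0, 3, n)
        slope = link * comp + rng.normal(0, 0.5, n) + site_conf * site
        df = pd.DataFrame(
            {
                "slope": slope,
                "comp": comp + (site_conf * site if site_conf else 0.0),
                "age": rng.normal(55, 10, n),
                "sex": rng.integers(0, 2, n),
                "site": [f"s{i}" for i in site],
            }
        )
        if two_groups:
            df["group"] = np.where(np.arange(n) % 2 == 0, "noncarrier", "presymptomatic")
        return df

    def test_null_link_calibrated(self):
        rej = 0
        for rep in range(20):
            rng = np.random.default_rng(700 + rep)
            res = predict_decline(self._frame(rng), "comp")
            rej += res.p_value < 0.05
        assert rej <= 4

    def test_planted_negative_link_recovered(self):
        for rep in range(3):
            rng = np.random.default_rng(800 + rep)
            res = predict_decline(self._frame(rng, link=-0.5), "comp")
            assert res.std_beta < 0
            assert res.p_value < 0.05

    def test_standardization_scale_invariance(self, rng):
        df = self._frame(rng, link=-0.4)
        a = predict_decline(df, "comp")
        df2 = df.assign(slope=df["slope"] * 10.0)
        b = predict_decline(df2, "comp")
        assert b.std_beta == pytest.approx(a.std_beta, abs=1e-10)
        assert b.t_stat == pytest.approx(a.t_stat, abs=1e-8)

    def test_site_confounding_controlled(self):
        rng = np.random.default_rng(31)
        df = self._frame(rng, link=0.0, site_conf=0.8)
        with_site = predict_decline(df, "comp")
        no_site = predict_decline(df.drop(columns="site"), "comp", site_col="missing")
        assert abs(with_site.std_beta) < abs(no_site.std_beta)
        assert abs(with_site.std_beta) < 0.2

    def test_site_label_permutation_invariance(self, rng):
        df = self._frame(rng, link=-0.3)
        relabel = {"s0": "zeta", "s1": "alpha", "s2": "mid"}
        df2 = df.assign(site=df["site"].map(relabel))
        a = predict_decline(df, "comp")
        b = predict_decline(df2, "comp")
        assert b.std_beta == pytest.approx(a.std_beta, abs=1e-10)

    def test_single_site_dropped_silently(self, rng):
        df = self._frame(rng, link=-0.3)
        df["site"] = "only"
        res = predict_decline(df, "comp")
        assert all(not t.startswith("site") for t in res.terms)

    def test_three_way_form_headline(self):
        rng = np.random.default_rng(44)
        df = self._frame(rng, two_groups=True)
        g = (df["group"] == "presymptomatic").astype(float)
        age_z = (df["age"] - df["age"].mean()) / df["age"].std(ddof=1)
        df["slope"] = df["slope"] + 0.8 * df["comp"] * age_z * g
        res = predict_decline(df, "comp_x_age_x_group")
        assert res.headline_term == "comp:age:group"
        assert res.p_value < 0.05 and res.std_beta > 0

    def test_rank_deficiency_names_terms(self, rng):
        df = self._frame(rng)
        df["age"] = 55.0  # constant -> z-scoring fails first
        with pytest.raises(ValueError):
            predict_decline(df, "comp")
        df2 = self._frame(rng)
        df2["sex"] = 1.0
        with pytest.raises(ValueError, match="sex"):
            predict_decline(df2, "comp")

    def test_unknown_form(self, rng):
        with pytest.raises(ValueError, match="form"):
            predict_decline(self._frame(rng), "quadratic")


def test_encode_site_reference_levels():
    cols, names = encode_site(pd.Series(["b", "a", "b", "c"]))
    assert names == ["site[b]", "site[c]"]
    assert cols.shape == (4, 2)
    cols1, names1 = encode_site(pd.Series(["only"] * 5))
    assert cols1.shape == (5, 0) and names1 == []
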