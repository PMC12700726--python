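"""Collinearity screen, count GLMM, weather GAM, Friedman test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nocturne.models import (
    fit_aci_gam,
    fit_count_glmm,
    friedman_behavior_test,
    vif,
)
from nocturne.synth import (
    SimulationConfig,
    gen_counts_and_attributes,
    gen_weather,
    planted_aci,
)


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        x1 = np.array([1.0, 1.0, -1.0, -1.0])
        x2 = np.array([1.0, -1.0, 1.0, -1.0])
        out = vif(pd.DataFrame({"x1": x1, "x2": x2, "x3": x1 * x2}))
        assert np.allclose(out.to_numpy(), 1.0)

    def test_duplicated_predictor_is_infinite_with_warning(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="collinearity"):
            out = vif(pd.DataFrame({"a": x, "b": x, "c": np.random.default_rng(0).normal(size=10)}))
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_known_correlation_closed_form(self):
        # construct two unit-variance predictors with exact sample r = 0.8
        n = 50
        rng = np.random.default_rng(1)
        e1, e2 = rng.normal(size=n), rng.normal(size=n)
        e1 = (e1 - e1.mean()) / e1.std()
        e2 = e2 - e2.mean()
        e2 -= (e2 @ e1) / (e1 @ e1) * e1  # orthogonalize
        e2 /= e2.std()
        x2 = 0.8 * e1 + np.sqrt(1 - 0.64) * e2
        out = vif(pd.DataFrame({"x1": e1, "x2": x2}))
        assert out["x1"] == pytest.approx(1 / (1 - 0.64), rel=1e-9)
        assert out["x2"] == pytest.approx(2.7778, rel=1e-3)

    def test_orthogonalized_design_always_unit(self, rng):
        x = rng.normal(size=(30, 4))
        q, _ = np.linalg.qr(x - x.mean(axis=0))
        out = vif(pd.DataFrame(q, columns=list("abcd")))
        assert np.allclose(out.to_numpy(), 1.0, atol=1e-8)


class TestFriedman:
    def test_identical_columns_give_zero_statistic(self):
        t = pd.DataFrame({"aggression": [5, 3], "social": [5, 3], "other": [5, 3]})
        stat, df, p = friedman_behavior_test(t)
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_consistent_dominance_hand_value(self):
        # 3 categories x 2 blocks, fixed within-block order: chi2 = 4.0
        t = pd.DataFrame({"aggression": [9, 7], "social": [5, 4], "other": [1, 2]})
        stat, df, p = friedman_behavior_test(t)
        assert stat == pytest.approx(4.0)
        assert df == 2

    def test_statistic_matches_rank_sum_formula_oracle(self, rng):
        # untied table: classical chi2 = 12/(n k (k+1)) * sum R_j^2 - 3 n (k+1)
        table = rng.permuted(np.tile([1.0, 5.0, 9.0], (6, 1)), axis=1) + rng.random((6, 3)) * 0.1
        t = pd.DataFrame(table, columns=["aggression", "social", "other"])
        stat, _, _ = friedman_behavior_test(t)
        ranks = stats.rankdata(table, axis=1)
        rj = ranks.sum(axis=0)
        n, k = table.shape
        expected = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3 * n * (k + 1)
        assert stat == pytest.approx(expected, abs=1e-9)

    def test_p_matches_monte_carlo_permutation_oracle(self, rng):
        table = rng.random((10, 3)) * 10
        t = pd.DataFrame(table, columns=["aggression", "social", "other"])
        stat, _, p = friedman_behavior_test(t)
        ref = []
        for _ in range(3000):
            permuted = rng.permuted(table, axis=1)
            s, _ = stats.friedmanchisquare(*[permuted[:, j] for j in range(3)])
            ref.append(s)
        p_oracle = np.mean(np.asarray(ref) >= stat - 1e-9)
        assert p == pytest.approx(p_oracle, abs=0.08)

    def test_monotone_within_block_transform_invariance(self, rng):
        table = rng.random((5, 3)) * 10
        t1 = pd.DataFrame(table, columns=["aggression", "social", "other"])
        t2 = pd.DataFrame(np.exp(table / 3), columns=["aggression", "social", "other"])
        assert friedman_behavior_test(t1)[0] == pytest.approx(friedman_behavior_test(t2)[0])

    def test_needs_three_categories_and_two_blocks(self):
        with pytest.raises(ValueError, match="3 categories"):
            friedman_behavior_test(pd.DataFrame({"aggression": [1], "social": [2]}))
        with pytest.raises(ValueError, match="2 hours"):
            friedman_behavior_test(
                pd.DataFrame({"aggression": [1], "social": [2], "other": [3]})
            )


@pytest.fixture(scope="module")
def planted_attrs():
    cfg = SimulationConfig()
    return gen_counts_and_attributes(cfg, 42, n_individuals=40, n_periods=20)


class TestCountGlmm:
    def test_recovers_generator_coefficients(self, planted_attrs):
        data, betas = planted_attrs
        res = fit_count_glmm(data)
        assert res.method == "glmm" and res.converged
        t = res.table.set_index("term")
        for term, key in [("sex", "sex"), ("age", "age"), ("centrality", "centrality"),
                          ("relatives", "relatives"), ("rank", "rank")]:
            est, se = t.loc[term, "estimate"], t.loc[term, "se"]
            assert abs(est - betas[key]) < 4 * se + 0.05
        assert np.sign(t.loc["sex", "estimate"]) == -1
        assert (res.vifs < 5).all()

    def test_non_integer_counts_rejected(self, planted_attrs):
        data, _ = planted_attrs
        bad = data.copy()
        bad["count"] = bad["count"].astype(float)
        bad.loc[0, "count"] = 1.5
        with pytest.raises(ValueError, match="integer"):
            fit_count_glmm(bad)

    def test_single_observation_per_individual_degrades_to_glm(self, planted_attrs):
        data, _ = planted_attrs
        one = data[data["period"] == 0]
        with pytest.warns(UserWarning, match="random intercept"):
            res = fit_count_glmm(one)
        assert res.method == "glm"
        assert np.isnan(res.random_sd)

    def test_offset_shifts_intercept_not_slopes(self, planted_attrs):
        data, _ = planted_attrs
        base = fit_count_glmm(data)
        shifted = data.copy()
        shifted["log_exposure"] = np.log(2.0)  # constant doubled exposure
        res = fit_count_glmm(shifted, offset="log_exposure")
        t0 = base.table.set_index("term")["estimate"]
        t1 = res.table.set_index("term")["estimate"]
        for term in ["rank", "sex", "age", "centrality", "relatives"]:
            assert t1[term] == pytest.approx(t0[term], abs=1e-4)
        assert t1["(Intercept)"] == pytest.approx(t0["(Intercept)"] - np.log(2.0), abs=1e-4)


@pytest.fixture(scope="module")
def planted_fit():
    cfg = SimulationConfig()
    weather, truth = gen_weather(cfg, 11, n_hours=400)
    data = weather.copy()
    data["aci"] = planted_aci(weather, truth, 12)
    grid = np.linspace(-4, 4, 41)
    res = fit_aci_gam(data, grid={"meridional_wind": grid})
    return res, truth, grid


class TestAciGam:
    def test_planted_terms_retained(self, planted_fit):
        res, _, _ = planted_fit
        assert "s(meridional_wind)" in res.retained_terms
        assert "ti(temperature,humidity)" in res.retained_terms

    def test_recovered_smooth_tracks_truth(self, planted_fit):
        res, truth, grid = planted_fit
        eff = res.grid_effects["meridional_wind"]
        rho = np.corrcoef(eff, truth.meridional_effect(grid))[0, 1]
        assert rho > 0.9

    def test_reports_candidate_aics_and_trace(self, planted_fit):
        res, _, _ = planted_fit
        assert len(res.candidate_aics) == 4
        assert res.chosen_candidate in range(4)
        assert all("dropped" in step for step in res.removal_trace)
        assert np.isfinite(res.adj_r2)

    def test_stepwise_is_deterministic(self):
        cfg = SimulationConfig()
        weather, truth = gen_weather(cfg, 21, n_hours=250)
        data = weather.copy()
        data["aci"] = planted_aci(weather, truth, 22)
        r1 = fit_aci_gam(data)
        r2 = fit_aci_gam(data)
        assert r1.retained_terms == r2.retained_terms
        assert [s["dropped"] for s in r1.removal_trace] == [
            s["dropped"] for s in r2.removal_trace
        ]

    def test_insufficient_rows_rejected(self):
        cfg = SimulationConfig()
        weather, _ = gen_weather(cfg, 5, n_hours=30)
        weather["aci"] = 1.0
        with pytest.raises(ValueError, match="rows"):
            fit_aci_gam(weather)
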