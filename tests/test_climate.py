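"""Anomalies, exponential fits, Mann-Kendall and piecewise SEM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from peatfire import climate as cs
from peatfire.synthetic import SimConfig, simulate_zone_climate


def monthly_table(values_by_year, variable="water_deficit"):
    rows = []
    for year, val in values_by_year.items():
        for m in range(1, 13):
            rows.append({"year": year, "month": m, variable: val})
    return pd.DataFrame(rows)


class TestSummerAnomalies:
    def test_baseline_mean_maps_to_zero_and_units(self, rng):
        vals = {1958 + i: float(v) for i, v in
                enumerate(rng.normal(10, 2, 66))}
        monthly = monthly_table(vals)
        anom = cs.summer_anomalies(monthly)
        mean = anom.baseline_mean["water_deficit"]
        sd = anom.baseline_sd["water_deficit"]
        # a year sitting at baseline mean + 2 sd scores z = 2
        some_year = min(vals)
        z = (vals[some_year] - mean) / sd
        assert anom.z_scores.loc[some_year, "water_deficit"] == pytest.approx(z)
        assert anom.z_scores["water_deficit"].mean() == pytest.approx(0, abs=1e-9)

    def test_hand_example(self):
        vals = dict.fromkeys(range(1958, 2024), 10.0)
        vals.update({1990 + i: 10 + [-2, 2, -2, 2][i % 4] for i in range(20)})
        monthly = monthly_table(vals)
        anom = cs.summer_anomalies(monthly)
        mean = anom.baseline_mean["water_deficit"]
        sd = anom.baseline_sd["water_deficit"]
        x = 14.0
        expect = (x - mean) / sd
        # check the z formula directly on an injected value
        got = (x - anom.baseline_mean) / anom.baseline_sd
        assert got["water_deficit"] == pytest.approx(expect)

    def test_constant_series_raises(self):
        monthly = monthly_table(dict.fromkeys(range(1958, 2024), 5.0))
        with pytest.raises(ValueError, match="zero baseline"):
            cs.summer_anomalies(monthly)

    def test_short_baseline_rejected(self, rng):
        monthly = monthly_table({2000 + i: float(i) for i in range(10)})
        with pytest.raises(ValueError):
            cs.summer_anomalies(monthly, baseline_years=(2000, 2009))


class TestFitExponential:
    def test_noiseless_recovery(self, rng):
        z = rng.normal(size=23)
        ba = np.exp(1.0 + 0.5 * z)
        fit = cs.fit_exponential(ba, z)
        assert fit.a == pytest.approx(1.0, abs=1e-9)
        assert fit.b == pytest.approx(0.5, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            cs.fit_exponential(np.ones(3), np.zeros(3))

    def test_zero_ba_offset_recorded(self, rng):
        z = rng.normal(size=12)
        ba = np.exp(0.5 * z)
        ba[0] = 0.0
        fit = cs.fit_exponential(ba, z)
        assert fit.offset == pytest.approx(ba[ba > 0].min() / 2)

    def test_glm_log_link_agrees_on_noiseless_data(self, rng):
        z = rng.normal(size=30)
        ba = np.exp(0.8 + 0.4 * z)
        fit = cs.fit_exponential(ba, z, model="glm-log")
        assert fit.a == pytest.approx(0.8, abs=1e-6)
        assert fit.b == pytest.approx(0.4, abs=1e-6)


class TestMannKendall:
    def test_strictly_increasing_n5(self):
        res = cs.mann_kendall(np.arange(5, dtype=float))
        assert res.s == 10 and res.tau == 1.0

    def test_hand_computation_n4(self):
        res = cs.mann_kendall(np.array([1.0, 2.0, 3.0, 4.0]))
        assert res.s == 6
        assert res.var_s == pytest.approx(4 * 3 * 13 / 18)
        assert res.z == pytest.approx((6 - 1) / np.sqrt(4 * 3 * 13 / 18),
                                      abs=1e-4)
        assert res.z == pytest.approx(1.699, abs=2e-3)

    def test_reversal_negates_s_keeps_p(self, rng):
        x = rng.normal(size=20)
        fwd = cs.mann_kendall(x)
        rev = cs.mann_kendall(x[::-1])
        assert rev.s == -fwd.s
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_constant_series(self):
        res = cs.mann_kendall(np.ones(10))
        assert res.tau == 0.0 and res.p_value == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for n in (8, 20, 50):
            x = np.round(rng.normal(size=n), 1)  # ties likely
            res = cs.mann_kendall(x)
            s = sum(np.sign(x[j] - x[i])
                    for i in range(n) for j in range(i + 1, n))
            assert res.s == s
            # tie-corrected variance recomputed independently
            _, counts = np.unique(x, return_counts=True)
            var = (n * (n - 1) * (2 * n + 5)
                   - sum(t * (t - 1) * (2 * t + 5) for t in counts)) / 18
            assert res.var_s == pytest.approx(var)
            slopes = [(x[j] - x[i]) / (j - i)
                      for i in range(n) for j in range(i + 1, n)]
            assert res.sen_slope == pytest.approx(np.median(slopes))

    def test_sen_slope_on_linear_series(self):
        x = 0.04 * np.arange(20) + 9.0
        assert cs.mann_kendall(x).sen_slope == pytest.approx(0.04)


class TestFisherC:
    def test_all_claims_at_one_gives_zero(self):
        c, df, p = cs.fisher_c([1.0, 1.0, 1.0])
        assert c == 0.0 and p == pytest.approx(1.0)

    def test_half_half_closed_form(self):
        c, df, p = cs.fisher_c([0.5, 0.5])
        assert c == pytest.approx(-2 * 2 * np.log(0.5), abs=1e-9)
        assert df == 4
        # chi-square df=4 survival: e^{-C/2} (1 + C/2)
        assert p == pytest.approx(np.exp(-c / 2) * (1 + c / 2), abs=1e-9)
        assert p == pytest.approx(0.597, abs=1e-3)

    def test_reported_c16_gives_p_020(self):
        # C = 20.49 at 16 degrees of freedom is a non-rejecting fit
        assert stats.chi2.sf(20.49, 16) == pytest.approx(0.20, abs=0.005)

    def test_nonnegative(self, rng):
        ps = rng.uniform(1e-6, 1, 10)
        c, _, _ = cs.fisher_c(ps)
        assert c >= 0


class TestPiecewiseSem:
    @pytest.fixture(scope="class")
    def fit(self):
        cfg = SimConfig(rng_seed=21)
        data = simulate_zone_climate(cfg)
        return cs.piecewise_sem(data, cs.default_sem_spec())

    def test_recovers_generator_path_signs(self, fit):
        assert fit.beta("water_deficit", "dc") > 0
        assert fit.beta("water_deficit", "pdsi") < 0
        assert fit.beta("dc", "log_total_ba") > 0
        assert fit.beta("pdsi", "log_peat_ba") < 0

    def test_conditional_r2_at_least_marginal(self, fit):
        for node in fit.nodes.values():
            assert node.conditional_r2 >= node.marginal_r2 - 1e-12

    def test_df_is_twice_claim_count(self, fit):
        assert fit.df == 2 * len(fit.independence_claims)

    def test_endogenous_covariance_reported_both_ways(self, fit):
        assert "corr(log_total_ba,log_peat_ba)" in fit.endogenous_cov
        assert "partial_corr(log_total_ba,log_peat_ba)" in fit.endogenous_cov

    def test_cyclic_spec_rejected(self):
        spec = cs.SemSpec(nodes=["a", "b"], paths=[("a", "b"), ("b", "a")])
        with pytest.raises(cs.CyclicGraphError):
            spec.graph()

    def test_missing_variable_rejected(self):
        data = pd.DataFrame({"a": [1.0, 2.0], "zone": ["w", "w"]})
        spec = cs.SemSpec(nodes=["a", "b"], paths=[("a", "b")])
        with pytest.raises(ValueError, match="missing"):
            cs.piecewise_sem(data, spec)

    def test_ols_paths_use_plain_regression(self, fit):
        assert fit.nodes["dc"].family == "ols"
        assert fit.nodes["pdsi"].family == "ols"
        assert fit.nodes["log_peat_ba"].family == "lmm"
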