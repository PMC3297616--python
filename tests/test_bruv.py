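"""BRUV reserve-effect analysis: summaries, GLMs, bootstrap, environment."""

import numpy as np
import pandas as pd
import pytest

import reeftrace.bruv as bruv
from reeftrace.bruv import (
    AREA_PROPORTIONAL_N, OBSERVED_SITE_COUNTS, bootstrap_density,
    compare_environments, deployments_from_counts, fit_env_glm_reserve_subset,
    fit_reserve_glm, summarize_sites,
)
from reeftrace.simulate import BruvSimConfig, SiteSpec, simulate_bruv


@pytest.fixture(scope="module")
def observed():
    return deployments_from_counts(OBSERVED_SITE_COUNTS)


class TestSummaries:
    def test_observed_site_rates(self, observed):
        summ = summarize_sites(observed).set_index("site")
        assert summ.loc["GRMR", "percent_present"] == 32.0
        assert summ.loc["SWC", "percent_present"] == 4.0
        assert summ.loc["reserve", "n_present"] == 29
        assert summ.loc["fished", "n_present"] == 8

    def test_rates_recompose_to_stratum_totals(self, observed):
        summ = summarize_sites(observed).set_index("site")
        res = summ.loc[["GRMR", "CCMR"]]
        assert res["n_present"].sum() == summ.loc["reserve", "n_present"]
        assert res["n_deployments"].sum() == summ.loc["reserve", "n_deployments"]

    def test_empty_site_flagged(self, observed):
        empty = observed[observed["site"] != "TU"]
        summ = summarize_sites(pd.concat(
            [empty, observed[observed["site"] == "TU"].iloc[0:0]]))
        assert "TU" not in set(summ["site"])  # truly absent sites drop out
        zero = summarize_sites(observed.iloc[0:0].assign(site="X"))
        assert zero.empty or zero["undefined"].all()


class TestReserveGLM:
    def test_reserve_term_significant_on_observed_counts(self, observed):
        fit = fit_reserve_glm(observed)
        tab = fit.deviance_table.set_index("term")
        assert tab.loc["reserve", "p"] < 0.05
        assert tab.loc["reserve", "deviance"] > 3.84
        assert tab.loc["location_nested", "df"] == 2

    def test_identical_rates_give_null_reserve_deviance(self):
        dep = deployments_from_counts({
            "A": (50, 10, True), "B": (50, 10, True),
            "C": (50, 10, False), "D": (50, 10, False)})
        fit = fit_reserve_glm(dep)
        assert fit.deviance_table.set_index("term").loc["reserve", "deviance"] == \
            pytest.approx(0.0, abs=1e-8)

    def test_deviance_additivity(self, observed):
        fit = fit_reserve_glm(observed)
        total = fit.deviance_table["deviance"].sum() + fit.deviance
        assert total == pytest.approx(fit.null_deviance, rel=1e-9)


class TestBootstrap:
    def test_same_seed_bit_identical(self, observed):
        a = bootstrap_density(observed, AREA_PROPORTIONAL_N, n_reps=200, seed=42)
        b = bootstrap_density(observed, AREA_PROPORTIONAL_N, n_reps=200, seed=42)
        assert np.array_equal(a.p_values, b.p_values)
        assert a.fraction_significant == b.fraction_significant

    def test_full_data_subsample_has_no_resampling_variance(self, observed):
        full_n = {s: 50 for s in OBSERVED_SITE_COUNTS}
        res = bootstrap_density(observed, full_n, n_reps=50, seed=1, replace=False)
        assert res.fraction_significant in (0.0, 1.0)
        assert len(np.unique(res.p_values)) == 1

    def test_all_absent_data_never_significant(self):
        dep = deployments_from_counts({
            "A": (50, 0, True), "B": (50, 0, True),
            "C": (50, 0, False), "D": (50, 0, False)})
        res = bootstrap_density(dep, {"A": 25, "B": 25, "C": 50, "D": 30},
                                n_reps=100, seed=3)
        assert res.fraction_significant == 0.0

    def test_oversampling_without_replacement_rejected(self, observed):
        with pytest.raises(ValueError, match="without replacement"):
            bootstrap_density(observed, {"GRMR": 60, "CCMR": 25, "TU": 50, "SWC": 30},
                              n_reps=10, seed=0, replace=False)

    def test_per_replicate_test_matches_glm_lrt(self, observed):
        # the closed-form two-group LRT equals the GLM deviance test
        import statsmodels.api as sm
        from scipy import stats
        from reeftrace.bruv import _binomial_lrt_p
        y = observed["presence"].to_numpy(float)
        x = observed["reserve"].to_numpy(float)
        g1 = sm.GLM(y, np.column_stack([np.ones_like(x), x]),
                    family=sm.families.Binomial()).fit()
        g0 = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
        want = stats.chi2.sf(g0.deviance - g1.deviance, 1)
        got = _binomial_lrt_p(29, 100, 8, 100)
        assert got == pytest.approx(want, rel=1e-10)

    def test_power_monotone_in_odds_ratio(self):
        from reeftrace.simulate import reserve_test_rate
        base = 0.10
        rates = []
        for i, odds_ratio in enumerate([1, 2, 5, 10]):
            odds = odds_ratio * base / (1 - base)
            p_res = odds / (1 + odds)
            cfg = BruvSimConfig(sites={
                "A": SiteSpec(True, 50, p_res), "B": SiteSpec(True, 50, p_res),
                "C": SiteSpec(False, 50, base), "D": SiteSpec(False, 50, base)})
            rates.append(reserve_test_rate(cfg, n_sim=150, seed=100 + i))
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > 0.8


class TestEnvironment:
    def test_single_site_rejected(self):
        df = simulate_bruv(BruvSimConfig(), 1)
        with pytest.raises(ValueError, match="2 sites"):
            compare_environments(df[df["site"] == "GRMR"], "salinity")

    def test_shifted_site_detected_by_tukey(self):
        cfg = BruvSimConfig()
        df = simulate_bruv(cfg, 11)
        anova, tukey = compare_environments(df, "temp_start")
        assert anova["p"].iloc[0] < 0.001
        swc = tukey[(tukey["group1"] == "SWC") | (tukey["group2"] == "SWC")]
        assert swc["reject"].astype(bool).all()

    def test_homogeneous_covariate_type_one_error(self):
        # no site shifts: ANOVA at alpha=0.05 rejects at the nominal rate
        cfg = BruvSimConfig(site_env_shifts={})
        hits = 0
        n_sim = 300
        for s in range(n_sim):
            df = simulate_bruv(cfg, 10_000 + s)
            anova, _ = compare_environments(df, "salinity")
            hits += anova["p"].iloc[0] < 0.05
        rate = hits / n_sim
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sim)


class TestEnvGLM:
    def test_structure_matches_reserve_subset(self):
        df = simulate_bruv(BruvSimConfig(), 23)
        fit = fit_env_glm_reserve_subset(df)
        n = int((df["reserve"] & df["env_complete"]).sum())
        assert len(fit.deviance_table) == 6
        assert fit.deviance_table["resid_df"].iloc[0] == n - 1 - 1
        total = fit.deviance_table["deviance"].sum() + fit.deviance
        assert total == pytest.approx(fit.null_deviance, rel=1e-6)

    def test_constant_flow_rejected(self):
        df = simulate_bruv(BruvSimConfig(), 2)
        df["flow_velocity"] = 0.2
        with pytest.raises(ValueError, match="flow"):
            fit_env_glm_reserve_subset(df)
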