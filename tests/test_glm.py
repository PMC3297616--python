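"""GLM fitting, sequential deviance decomposition and the inclusion rule."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import reeftrace.glm as glm


def brute_force_mle(y, X, family):
    """Direct likelihood maximization, independent of the IRLS path."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)

    if family == "binomial_logit":
        def nll(b):
            eta = X @ b
            return -(y @ eta - np.logaddexp(0, eta).sum())
    else:
        def nll(b):
            r = y - X @ b
            return 0.5 * (r @ r)

    res = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 5000})
    return res.x


def random_dataset(rng, n, family):
    df = pd.DataFrame({
        "x1": rng.normal(size=n),
        "x2": rng.normal(size=n),
        "g": rng.choice(["a", "b", "c"], size=n),
    })
    eta = 0.3 + 0.8 * df["x1"] - 0.5 * df["x2"] + (df["g"] == "b") * 0.7
    if family == "binomial_logit":
        df["y"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    else:
        df["y"] = eta + rng.normal(0, 0.7, n)
    return df


class TestFitGLM:
    def test_intercept_only_binomial_matches_closed_form(self):
        # deviance of k successes in n: -2[k log p + (n-k) log(1-p)], p = k/n
        k, n = 7, 20
        df = pd.DataFrame({"y": [1] * k + [0] * (n - k)})
        fit = glm.fit_glm(df, "y", [])
        p = k / n
        want = -2 * (k * np.log(p) + (n - k) * np.log(1 - p))
        assert fit.null_deviance == pytest.approx(want, rel=1e-10)
        assert fit.deviance == pytest.approx(want, rel=1e-10)

    @pytest.mark.parametrize("family", ["binomial_logit", "gaussian"])
    def test_matches_brute_force_optimizer(self, family):
        rng = np.random.default_rng(17)
        for n in (20, 35, 50):
            df = random_dataset(rng, n, family)
            fit = glm.fit_glm(df, "y", ["x1", "x2", "g"], family=family)
            X, _ = glm.design_matrix(df, ["x1", "x2", "g"])
            want = brute_force_mle(df["y"], X, family)
            assert np.allclose(fit.params.to_numpy(), want, atol=1e-5)

    @pytest.mark.parametrize("family", ["binomial_logit", "gaussian"])
    def test_deviance_additivity(self, family):
        rng = np.random.default_rng(3)
        df = random_dataset(rng, 120, family)
        fit = glm.fit_glm(df, "y", ["x1", "x2", "g"], family=family)
        total = fit.deviance_table["deviance"].sum() + fit.deviance
        assert total == pytest.approx(fit.null_deviance, rel=1e-9)
        assert fit.deviance_table["resid_dev"].iloc[-1] == pytest.approx(
            fit.deviance, rel=1e-9)

    def test_collinear_predictor_raises_naming_column(self):
        rng = np.random.default_rng(0)
        df = random_dataset(rng, 40, "gaussian")
        df["x3"] = 2.0 * df["x1"]
        with pytest.raises(glm.RankDeficiencyError, match="x3"):
            glm.fit_glm(df, "y", ["x1", "x2", "x3"], family="gaussian")

    def test_gaussian_uses_f_tests(self):
        rng = np.random.default_rng(8)
        df = random_dataset(rng, 60, "gaussian")
        fit = glm.fit_glm(df, "y", ["x1"], family="gaussian")
        row = fit.deviance_table.iloc[0]
        f = (row["deviance"] / row["df"]) / fit.scale
        want = stats.f.sf(f, row["df"], fit.n - len(fit.params))
        assert row["p"] == pytest.approx(want, rel=1e-9)

    def test_separation_yields_finite_coefficients(self):
        df = pd.DataFrame({"x": [-2., -1., -0.5, 0.5, 1., 2.],
                           "y": [0, 0, 0, 1, 1, 1]})
        with pytest.warns(UserWarning, match="separation"):
            fit = glm.fit_glm(df, "y", ["x"])
        assert np.all(np.isfinite(fit.params))
        assert fit.separation


class TestPercentDeviance:
    def test_published_table_arithmetic(self):
        tab = glm.deviance_table_from_drops(
            700.62, [("days", 1, 18.06), ("ldist", 1, 158.43),
                     ("shark_type", 3, 6.13), ("habitat", 2, 7.05)], n=592)
        assert glm.percent_deviance(tab, "ldist") == pytest.approx(158.43 / 700.62)
        # published drops are rounded to 2 dp, so the residual carries ~0.03 slack
        assert tab["resid_dev"].iloc[-1] == pytest.approx(510.94, abs=0.03)
        assert tab["resid_df"].iloc[-1] == 584

    def test_null_model_has_no_terms(self):
        rng = np.random.default_rng(1)
        df = random_dataset(rng, 30, "binomial_logit")
        fit = glm.fit_glm(df, "y", [])
        assert fit.deviance_table.empty


class TestInclusionRule:
    @pytest.mark.parametrize("p,pct,daic,dbic,want", [
        (0.01, 0.05, +1.0, +1.0, True),    # significant and >2% deviance
        (0.11, 0.01, -2.0, +1.0, True),    # AIC improves (weak term retained)
        (0.11, 0.01, +1.0, -2.0, True),    # BIC improves
        (0.01, 0.01, +1.0, +1.0, False),   # significant but small, no IC gain
        (0.50, 0.001, +3.0, +5.0, False),  # nothing speaks for it
    ])
    def test_three_clause_truth_table(self, p, pct, daic, dbic, want):
        got, rationale = glm.inclusion_decision(p, pct, daic, dbic)
        assert got is want
        assert ("excluded" in rationale) is (not want)

    def test_select_model_reports_rationale_per_term(self):
        rng = np.random.default_rng(12)
        df = random_dataset(rng, 300, "binomial_logit")
        df["noise"] = rng.normal(size=len(df))
        sel = glm.select_model(df, "y", ["x1", "x2", "noise"])
        by_term = {d.term: d for d in sel.decisions}
        assert by_term["x1"].included
        assert not by_term["noise"].included
        assert "excluded" in by_term["noise"].rationale

    def test_aic_tie_resolved_by_order(self):
        rng = np.random.default_rng(2)
        df = random_dataset(rng, 50, "binomial_logit")
        f1 = glm.fit_glm(df, "y", ["x1"])
        f2 = glm.fit_glm(df, "y", ["x1"])
        assert glm.best_by_aic([f1, f2]) is f1
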