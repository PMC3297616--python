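"""Fixed-effects GLMs with sequential (type-I) analysis of deviance.

Models are specified as an ordered list of term names over a DataFrame:
numeric columns enter as single covariates, string/categorical columns as
treatment-coded dummies, and ``"a:b"`` as the interaction of the two blocks.
The analysis-of-deviance table decomposes the null deviance term by term in
the declared order, exactly the way R's ``anova(glm_fit)`` prints it:
chi-square tests for binomial fits, F tests for gaussian fits.

Model fitting is delegated to statsmodels; this module owns the term
bookkeeping, the sequential decomposition, and the inclusion rule used for
model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient; names the aliased columns."""


def build_term(df: pd.DataFrame, term: str) -> pd.DataFrame:
    """Columns contributed by one term (numeric, factor dummies, or a:b)."""
    if ":" in term:
        left, right = term.split(":", 1)
        lb, rb = build_term(df, left), build_term(df, right)
        cols = {}
        for lc in lb.columns:
            for rc in rb.columns:
                cols[f"{lc}:{rc}"] = lb[lc].to_numpy(float) * rb[rc].to_numpy(float)
        return pd.DataFrame(cols, index=df.index)
    if term not in df.columns:
        raise KeyError(f"unknown term {term!r}")
    col = df[term]
    if pd.api.types.is_numeric_dtype(col) and not isinstance(col.dtype, pd.CategoricalDtype):
        return pd.DataFrame({term: col.to_numpy(float)}, index=df.index)
    if not isinstance(col.dtype, pd.CategoricalDtype):
        col = col.astype(str)
    # treatment coding: the first (or first declared category) level is baseline
    dummies = pd.get_dummies(col, prefix=term, prefix_sep="=",
                             drop_first=True, dtype=float)
    return dummies


def design_matrix(df: pd.DataFrame, terms: list[str]) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Intercept + term blocks in order; also the column names per term."""
    blocks = [pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index)]
    term_cols: dict[str, list[str]] = {}
    for t in terms:
        b = build_term(df, t)
        term_cols[t] = list(b.columns)
        blocks.append(b)
    X = pd.concat(blocks, axis=1)
    return X, term_cols


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    r = np.linalg.matrix_rank(arr)
    if r < arr.shape[1]:
        _, R = np.linalg.qr(arr)
        aliased = [X.columns[i] for i in range(arr.shape[1])
                   if abs(R[i, i]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise RankDeficiencyError(f"aliased column(s): {aliased}")


@dataclass
class ModelFit:
    """A fitted GLM (or mixed model) with its sequential deviance table.

    deviance_table columns: term, df, deviance, resid_df, resid_dev, p,
    percent_deviance (share of the null deviance).  Invariant: the term
    deviances plus the final residual deviance reconstitute the null
    deviance.
    """

    response: str
    family: str
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    deviance_table: pd.DataFrame
    null_deviance: float
    deviance: float
    llf: float
    aic: float
    bic: float
    n: int
    fitted: np.ndarray
    scale: float = 1.0
    random_terms: list[str] = field(default_factory=list)
    converged: bool = True
    separation: bool = False
    extra: dict = field(default_factory=dict)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = design_matrix(df, self.terms)
        X = X.reindex(columns=self.params.index, fill_value=0.0)
        eta = X.to_numpy(float) @ self.params.to_numpy(float)
        if self.family == "binomial_logit":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta

    def linear_predictor_se(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = design_matrix(df, self.terms)
        X = X.reindex(columns=self.params.index, fill_value=0.0).to_numpy(float)
        return np.sqrt(np.einsum("ij,jk,ik->i", X, self.cov_params.to_numpy(float), X))


@dataclass
class _GLMResult:
    params: np.ndarray
    bse: np.ndarray
    cov: np.ndarray
    deviance: float
    llf: float
    df_resid: int
    fittedvalues: np.ndarray

    def cov_params(self):
        return self.cov


def _wrap(model, res) -> _GLMResult:
    return _GLMResult(np.asarray(res.params), np.asarray(res.bse),
                      np.asarray(res.cov_params()), float(res.deviance),
                      float(res.llf), int(res.df_resid),
                      np.asarray(res.fittedvalues))


def _at_params(model, params) -> _GLMResult:
    """Evaluate GLM quantities at fixed coefficients (ridge-stabilized fits)."""
    y = model.endog
    X = model.exog
    mu = model.predict(params)
    w = np.clip(mu * (1 - mu), 1e-10, None) if isinstance(
        model.family, sm.families.Binomial) else np.ones(len(y))
    cov = np.linalg.pinv((X.T * w) @ X)
    return _GLMResult(np.asarray(params), np.sqrt(np.diag(cov)), cov,
                      float(model.family.deviance(y, mu)), float(model.loglike(params)),
                      int(len(y) - X.shape[1]), mu)


def _fit_one(y, X, family):
    if family == "binomial_logit":
        model = sm.GLM(y, X, family=sm.families.Binomial())
    elif family == "gaussian":
        model = sm.GLM(y, X, family=sm.families.Gaussian())
    else:
        raise ValueError(f"unknown family {family!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit()
            ok = bool(np.all(np.isfinite(res.params)))
            if ok and family == "binomial_logit":
                # coefficients drifting past +/-30 on the logit scale mean the
                # likelihood is flat along a separating direction
                ok = bool(np.all(np.abs(res.params) < 30))
        except Exception:
            ok = False
    if ok:
        return _wrap(model, res), False
    # quasi-separation: a whisper of ridge keeps coefficients finite
    reg = model.fit_regularized(alpha=1e-6, L1_wt=0.0)
    warnings.warn("separation detected; coefficients stabilized by ridge epsilon")
    return _at_params(model, np.asarray(reg.params)), True


def fit_glm(df: pd.DataFrame, response: str, terms: list[str],
            family: str = "binomial_logit") -> ModelFit:
    """Fit a GLM and decompose its deviance sequentially in term order.

    family "binomial_logit" for 0/1 responses (chi-square term tests) or
    "gaussian" for continuous responses such as log fraction-of-days
    (F term tests, deviance = residual sum of squares).
    """
    y = df[response].to_numpy(float)
    X_full, term_cols = design_matrix(df, terms)
    _check_rank(X_full)

    # nested fits: intercept-only, then cumulatively add each term
    devs, fits = [], []
    cols = ["Intercept"]
    for prefix_len in range(len(terms) + 1):
        if prefix_len > 0:
            cols = cols + term_cols[terms[prefix_len - 1]]
        res, sep = _fit_one(y, X_full[cols], family)
        devs.append(res.deviance)
        fits.append((res, sep))
    full, separation = fits[-1]
    null_dev = devs[0]

    resid_df_full = full.df_resid
    scale = full.deviance / resid_df_full if family == "gaussian" and resid_df_full > 0 else 1.0
    rows = []
    resid_df = len(y) - 1
    for i, t in enumerate(terms):
        drop = devs[i] - devs[i + 1]
        df_t = len(term_cols[t])
        resid_df -= df_t
        if family == "binomial_logit":
            p = stats.chi2.sf(drop, df_t)
        else:
            f = (drop / df_t) / scale
            p = stats.f.sf(f, df_t, resid_df_full)
        rows.append({"term": t, "df": df_t, "deviance": drop, "resid_df": resid_df,
                     "resid_dev": devs[i + 1], "p": p,
                     "percent_deviance": drop / null_dev if null_dev > 0 else 0.0})
    table = pd.DataFrame(rows, columns=["term", "df", "deviance", "resid_df",
                                        "resid_dev", "p", "percent_deviance"])
    k = X_full.shape[1] + (1 if family == "gaussian" else 0)
    return ModelFit(
        response=response, family=family, terms=list(terms),
        params=pd.Series(full.params, index=X_full.columns),
        bse=pd.Series(full.bse, index=X_full.columns),
        cov_params=pd.DataFrame(np.asarray(full.cov_params()),
                                index=X_full.columns, columns=X_full.columns),
        deviance_table=table, null_deviance=null_dev, deviance=full.deviance,
        llf=full.llf, aic=-2 * full.llf + 2 * k, bic=-2 * full.llf + k * np.log(len(y)),
        n=len(y), fitted=np.asarray(full.fittedvalues), scale=scale,
        separation=separation,
    )


def deviance_table_from_drops(null_deviance: float,
                              drops: list[tuple[str, int, float]],
                              n: int, family: str = "binomial_logit") -> pd.DataFrame:
    """Sequential deviance table from per-term deviance drops.

    Reconstructs the same table ``fit_glm`` produces, from a null deviance
    and ordered (term, df, deviance) rows -- the form analysis-of-deviance
    tables are published in.  The residual deviance of each row is the null
    deviance minus the cumulative drops; percent deviance is each drop's
    share of the null deviance.
    """
    rows = []
    resid_dev = null_deviance
    resid_df = n - 1
    for term, df_t, drop in drops:
        resid_dev -= drop
        resid_df -= df_t
        rows.append({"term": term, "df": df_t, "deviance": drop,
                     "resid_df": resid_df, "resid_dev": resid_dev,
                     "p": stats.chi2.sf(drop, df_t) if family == "binomial_logit" else np.nan,
                     "percent_deviance": drop / null_deviance})
    return pd.DataFrame(rows)


def percent_deviance(fit: ModelFit | pd.DataFrame, term: str) -> float:
    """Share of the null deviance attributed to one term (sequential)."""
    tab = fit if isinstance(fit, pd.DataFrame) else fit.deviance_table
    row = tab[tab["term"] == term]
    if row.empty:
        raise KeyError(f"term {term!r} not in fit")
    return float(row["percent_deviance"].iloc[0])


@dataclass
class TermDecision:
    term: str
    included: bool
    p: float
    pct_deviance: float
    delta_aic: float
    delta_bic: float
    rationale: str


def inclusion_decision(p: float, pct_deviance: float, delta_aic: float,
                       delta_bic: float, alpha: float = 0.05,
                       pct_threshold: float = 0.02) -> tuple[bool, str]:
    """The three-clause inclusion rule for one candidate term.

    Include if (significant AND explains more than the deviance threshold)
    OR the AIC improves OR the BIC improves.  Returns (included, rationale).
    """
    clauses = []
    if p < alpha and pct_deviance > pct_threshold:
        clauses.append(f"significant (p={p:.3g}) and "
                       f">{pct_threshold:.0%} deviance ({pct_deviance:.1%})")
    if delta_aic < 0:
        clauses.append(f"AIC improves ({delta_aic:+.2f})")
    if delta_bic < 0:
        clauses.append(f"BIC improves ({delta_bic:+.2f})")
    if clauses:
        return True, "; ".join(clauses)
    return False, (f"excluded: p={p:.3g}, {pct_deviance:.1%} deviance, "
                   f"dAIC={delta_aic:+.2f}, dBIC={delta_bic:+.2f}")


@dataclass
class SelectionResult:
    fit: ModelFit
    decisions: list[TermDecision]

    @property
    def terms(self) -> list[str]:
        return self.fit.terms


def select_model(df: pd.DataFrame, response: str, candidate_terms: list[str],
                 family: str = "binomial_logit", alpha: float = 0.05,
                 pct_threshold: float = 0.02) -> SelectionResult:
    """Forward inclusion in declared order under a three-clause rule.

    A term enters if it is significant AND explains more than
    ``pct_threshold`` of the null deviance, OR if it improves the AIC, OR if
    it improves the BIC.  The rationale string per term records which clause
    admitted (or none excluded) it.
    """
    included: list[str] = []
    decisions: list[TermDecision] = []
    base = fit_glm(df, response, included, family)
    for t in candidate_terms:
        trial = fit_glm(df, response, included + [t], family)
        row = trial.deviance_table.iloc[-1]
        d_aic = trial.aic - base.aic
        d_bic = trial.bic - base.bic
        take, rationale = inclusion_decision(float(row["p"]), float(row["percent_deviance"]),
                                             d_aic, d_bic, alpha, pct_threshold)
        decisions.append(TermDecision(t, take, float(row["p"]),
                                      float(row["percent_deviance"]),
                                      float(d_aic), float(d_bic), rationale))
        if take:
            included.append(t)
            base = trial
    return SelectionResult(base, decisions)


def best_by_aic(fits: list[ModelFit]) -> ModelFit:
    """AIC-best fit; ties resolved by declaration order (first wins)."""
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged fits to select from")
    best = usable[0]
    for f in usable[1:]:
        if f.aic < best.aic:
            best = f
    return best
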