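"""Mixed models by penalized likelihood with a Laplace approximation.

The shark x receiver detection analysis needs random effects that are
*crossed* (every shark meets every receiver): random intercepts by shark or
by receiver, and random slopes of log-distance by either.  The marginal
likelihood is maximized with the standard Laplace route: for candidate
variance parameters the joint penalized log-likelihood is maximized over
(fixed effects, spherical random effects) by Newton iterations, and the
marginal log-likelihood is approximated at that mode; a derivative-free
outer search runs over the log standard deviations.

Random-term syntax: ``"1|shark_id"`` (random intercept by shark; the bare
column name is an alias) or ``"ldist|shark_id"`` (random slope of ldist by
shark).  Each term has one variance; terms are independent.

Gaussian responses are supported with the residual SD profiled into the
outer search (the Laplace approximation is exact there), which keeps one
code path for both stages of the delta-lognormal analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .glm import ModelFit, design_matrix


class ConvergenceError(RuntimeError):
    """The penalized-likelihood fit failed to converge."""


def _parse_random(term: str) -> tuple[str | None, str]:
    if "|" in term:
        covar, group = (s.strip() for s in term.split("|", 1))
        return (None if covar in ("1", "") else covar), group
    return None, term.strip()


def _random_block(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    covar, group = _parse_random(term)
    levels = pd.Categorical(df[group].astype(str))
    Z = np.zeros((len(df), len(levels.categories)))
    Z[np.arange(len(df)), levels.codes] = 1.0
    if covar is not None:
        Z *= df[covar].to_numpy(float)[:, None]
    names = [f"{term}[{c}]" for c in levels.categories]
    return Z, names


def _inner_newton(y, X, Zs, sigmas, family, sigma_e=1.0, tol=1e-9, maxiter=100):
    """Maximize the joint penalized log-likelihood over (beta, v).

    Random effects are spherical: u_j = sigma_j * v_j with penalty ||v||^2/2.
    Returns (delta, eta, loglik_cond, penalty, logdet_term).
    """
    n, p = X.shape
    Zt = np.hstack([s * Z for Z, s in zip(Zs, sigmas)]) if Zs else np.zeros((n, 0))
    q = Zt.shape[1]
    M = np.hstack([X, Zt])
    pen = np.concatenate([np.zeros(p), np.ones(q)])
    delta = np.zeros(p + q)

    def cond_loglik(eta):
        if family == "binomial_logit":
            return float(y @ eta - np.logaddexp(0.0, eta).sum())
        r = y - eta
        return float(-0.5 * len(y) * np.log(2 * np.pi * sigma_e**2)
                     - 0.5 * (r @ r) / sigma_e**2)

    def weights(eta):
        if family == "binomial_logit":
            mu = 1.0 / (1.0 + np.exp(-eta))
            return mu, np.clip(mu * (1 - mu), 1e-10, None)
        return eta, np.full(len(eta), 1.0 / sigma_e**2)

    eta = M @ delta
    obj = cond_loglik(eta) - 0.5 * (pen * delta**2).sum()
    for _ in range(maxiter):
        mu, w = weights(eta)
        grad = M.T @ ((y - mu) if family == "binomial_logit" else (y - eta) / sigma_e**2)
        grad -= pen * delta
        H = (M.T * w) @ M + np.diag(pen)
        H[np.diag_indices_from(H)] += 1e-10
        step = np.linalg.solve(H, grad)
        # step-halving keeps the penalized objective monotone
        for _ in range(30):
            new = delta + step
            eta_new = M @ new
            obj_new = cond_loglik(eta_new) - 0.5 * (pen * new**2).sum()
            if obj_new >= obj - 1e-12:
                break
            step *= 0.5
        else:
            break
        moved = np.max(np.abs(new - delta))
        delta, eta, obj = new, eta_new, obj_new
        if moved < tol:
            break
    mu, w = weights(eta)
    if q:
        Hvv = (Zt.T * w) @ Zt + np.eye(q)
        sign, logdet = np.linalg.slogdet(Hvv)
        if sign <= 0:
            raise ConvergenceError("indefinite Hessian in Laplace step")
    else:
        logdet = 0.0
    v = delta[p:]
    return delta, eta, cond_loglik(eta), 0.5 * float(v @ v), 0.5 * logdet, M, w, pen


def fit_glmm(df: pd.DataFrame, response: str, fixed_terms: list[str],
             random_terms: list[str], family: str = "binomial_logit",
             fixed_sigmas: dict[str, float] | None = None) -> ModelFit:
    """Fit a GLMM by Laplace-approximate maximum likelihood.

    fixed_sigmas pins chosen random-term SDs (e.g. to 0, the degenerate
    limit in which the fit must agree with the fixed-effects GLM).  The
    returned ModelFit carries the estimated SDs in ``extra["sigmas"]``
    (and ``extra["sigma_resid"]`` for gaussian fits).
    """
    y = df[response].to_numpy(float)
    X_df, _ = design_matrix(df, fixed_terms)
    X = X_df.to_numpy(float)
    Zs, _names = [], []
    for t in random_terms:
        Z, nm = _random_block(df, t)
        Zs.append(Z)
        _names.append(nm)
    fixed_sigmas = fixed_sigmas or {}
    free = [i for i, t in enumerate(random_terms) if t not in fixed_sigmas]

    def sigma_vec(theta):
        s = np.empty(len(random_terms))
        for i, t in enumerate(random_terms):
            s[i] = fixed_sigmas.get(t, np.nan)
        s[free] = np.exp(theta[: len(free)])
        return s

    is_gauss = family == "gaussian"

    def neg_marginal(theta):
        s = sigma_vec(theta)
        se = np.exp(theta[-1]) if is_gauss else 1.0
        try:
            _, _, ll, penalty, half_logdet, _, _, _ = _inner_newton(
                y, X, Zs, s, family, sigma_e=se)
        except (ConvergenceError, np.linalg.LinAlgError):
            return 1e10
        return -(ll - penalty - half_logdet)

    n_theta = len(free) + (1 if is_gauss else 0)
    converged = True
    if n_theta:
        theta0 = np.zeros(n_theta)
        if is_gauss:
            theta0[-1] = np.log(max(np.std(y), 1e-3))
        res = optimize.minimize(neg_marginal, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000})
        converged = bool(res.success)
        theta = res.x
        llf = -res.fun
    else:
        theta = np.zeros(0)
        llf = -neg_marginal(theta)
    s = sigma_vec(theta)
    se = float(np.exp(theta[-1])) if is_gauss else 1.0
    delta, eta, ll, penalty, half_logdet, M, w, pen = _inner_newton(
        y, X, Zs, s, family, sigma_e=se)
    p = X.shape[1]
    H = (M.T * w) @ M + np.diag(pen)
    H[np.diag_indices_from(H)] += 1e-10
    cov = np.linalg.inv(H)[:p, :p]

    k = p + n_theta
    n = len(y)
    fitted = 1.0 / (1.0 + np.exp(-eta)) if family == "binomial_logit" else eta
    return ModelFit(
        response=response, family=family, terms=list(fixed_terms),
        params=pd.Series(delta[:p], index=X_df.columns),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=X_df.columns),
        cov_params=pd.DataFrame(cov, index=X_df.columns, columns=X_df.columns),
        deviance_table=pd.DataFrame(columns=["term", "df", "deviance", "resid_df",
                                             "resid_dev", "p", "percent_deviance"]),
        null_deviance=np.nan, deviance=-2 * llf, llf=llf,
        aic=-2 * llf + 2 * k, bic=-2 * llf + k * np.log(n), n=n,
        fitted=fitted, scale=se**2, random_terms=list(random_terms),
        converged=converged,
        extra={"sigmas": dict(zip(random_terms, s)),
               **({"sigma_resid": se} if is_gauss else {})},
    )
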