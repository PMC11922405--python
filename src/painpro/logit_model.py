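"""Adjusted analysis of the dichotomous opioid-use endpoint.

A multivariable logistic model with the same covariates as the primary
analysis, reference level GA-o.  Group effects are reported two ways:
odds ratios with Wald CIs, and adjusted percentage-point differences via
g-computation (marginal standardisation): for each subgroup every
record's subgroup is set counterfactually to that level, predicted
probabilities are averaged, and pairwise differences of those marginal
probabilities are scaled to percentage points.  CIs for the percentage
differences come from a seeded nonparametric bootstrap over records by
default, or from the delta method.

Near-certain outcomes (subgroups with ~99 % use) make separation a real
possibility, so a ridge-penalised likelihood fallback is mandatory
behaviour: it triggers automatically, with a warning and a method tag,
never a silent failure.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
import statsmodels.api as sm

from .errors import PainProError
from .model_base import (FitResult, ModelSpec, build_frame, check_degenerate,
                         design_matrix, grid_design)
from .registry import complete_case_subset

#: linear-predictor magnitude beyond which we treat ML as separated
_SEPARATION_COEF = 15.0


def default_opioid_spec() -> ModelSpec:
    """Same covariates as the primary model, outcome = opioid use.

    The PACU/ward opioid indicators are *components* of the outcome here,
    so they drop out of the covariate list.
    """
    return ModelSpec(
        outcome="opioid_use",
        factors=["sex", "enrolment_period", "nonopioid_pre_intra", "nonopioid_post",
                 "oands_flag"],
    )


def _ridge_logit(y: np.ndarray, X: np.ndarray, alpha: float = 1.0, maxiter: int = 200):
    """Newton solver for L2-penalised logistic regression.

    The intercept is unpenalised.  Returns ``(beta, cov)`` with the
    covariance from the inverse penalised observed information.
    """
    n, p = X.shape
    pen = np.full(p, alpha)
    pen[0] = 0.0
    beta = np.zeros(p)
    for _ in range(maxiter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu) - pen * beta
        W = mu * (1 - mu)
        H = (X * W[:, None]).T @ X + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(grad)) < 1e-8:
            break
    cov = np.linalg.inv(H)
    return beta, cov


def fit_logistic(data: pd.DataFrame, spec: ModelSpec | None = None, *,
                 reference: str = "GA-o", ridge_alpha: float = 1.0) -> FitResult:
    """Maximum-likelihood logistic fit of opioid use on complete cases.

    ``reference`` names the subgroup coded as the reference category.
    On (quasi-)separation the fit switches to ridge-penalised likelihood
    with a warning; the result's ``method`` tag records which path ran.
    """
    spec = spec or default_opioid_spec()
    cc, cc_report = complete_case_subset(data, spec.variables())
    if len(cc) == 0:
        raise PainProError("no complete cases for the requested model")
    frame, factor_levels, cont_means = build_frame(cc, spec)
    # put the reference level first so treatment coding is relative to it
    glv = factor_levels[spec.group]
    if reference not in glv:
        raise PainProError(f"reference level {reference!r} not present in data")
    glv = [reference] + [g for g in glv if g != reference]
    frame[spec.group] = pd.Categorical(frame[spec.group].astype(object), categories=glv)
    factor_levels[spec.group] = glv
    check_degenerate(frame, spec)

    y = cc[spec.outcome].astype(float).to_numpy()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise PainProError(f"outcome {spec.outcome!r} must be binary 0/1")
    X, colnames, design_info = design_matrix(frame, spec)

    method = "logit-ml"
    separated = y.min() == y.max()
    params = cov = None
    if not separated:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")  # PerfectSeparationWarning -> error
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            if (not res.converged) or np.max(np.abs(res.params)) > _SEPARATION_COEF:
                separated = True
            else:
                params, cov = np.asarray(res.params), np.asarray(res.cov_params())
        except Exception:
            separated = True
    if separated:
        warnings.warn("separation detected in logistic fit; "
                      "using ridge-penalised likelihood", stacklevel=2)
        params, cov = _ridge_logit(y, X, alpha=ridge_alpha)
        method = "logit-ridge"

    return FitResult(
        params=pd.Series(params, index=colnames),
        cov=pd.DataFrame(cov, index=colnames, columns=colnames),
        phi=None, link="logit", n_used=len(cc), n_effective=None,
        resid_df=len(cc) - X.shape[1], spec=spec, design_info=design_info,
        factor_levels=factor_levels, cont_means=cont_means, frame=frame,
        method=method, converged=True,
        diagnostics={"complete_case": cc_report, "outcome_mean": float(y.mean()),
                     "_y": y},
    )


def odds_ratios(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """exp(coefficient) with Wald confidence intervals for every model term."""
    z = norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(np.diag(fit.cov.to_numpy()))
    out = pd.DataFrame({
        "term": fit.params.index,
        "or": np.exp(fit.params.to_numpy()),
        "ci_low": np.exp(fit.params.to_numpy() - z * se),
        "ci_high": np.exp(fit.params.to_numpy() + z * se),
    })
    out["method"] = fit.method
    return out[out["term"] != "Intercept"].reset_index(drop=True)


def _marginal_probs(params: np.ndarray, fit: FitResult,
                    frame: pd.DataFrame) -> np.ndarray:
    """g-computation: counterfactually assign each subgroup level to all records."""
    group = fit.spec.group
    levels = fit.factor_levels[group]
    out = np.empty(len(levels))
    for k, lv in enumerate(levels):
        cf = frame.copy()
        cf[group] = pd.Categorical([lv] * len(cf), categories=levels)
        Xcf = grid_design(fit.design_info, cf)
        out[k] = float(np.mean(expit(Xcf @ params)))
    return out


def risk_difference_contrasts(fit: FitResult, *, B: int = 1000, seed: int = 0,
                              ci: str = "bootstrap", adjust: str = "none",
                              level: float = 0.95,
                              max_failure_rate: float = 0.05) -> pd.DataFrame:
    """Adjusted percentage-point differences in opioid use between subgroups.

    Point estimates are g-computation marginal probabilities differenced
    pairwise and scaled by 100.  ``ci="bootstrap"`` (default) resamples
    records ``B`` times with the given seed, refitting (with automatic
    ridge fallback) each time; ``ci="delta"`` uses the delta method on
    the fitted covariance.  P-values are Wald tests from the respective
    SEs, optionally Bonferroni-adjusted.
    """
    group = fit.spec.group
    levels = fit.factor_levels[group]
    k = len(levels)
    beta = fit.params.to_numpy()
    probs = _marginal_probs(beta, fit, fit.frame)
    pairs = list(combinations(range(k), 2))
    diffs = {(i, j): 100.0 * (probs[i] - probs[j]) for i, j in pairs}

    if ci == "bootstrap":
        ses, los, his = _bootstrap_cis(fit, pairs, B, seed, level, max_failure_rate)
        method = f"gcomp+bootstrap(B={B})"
    elif ci == "delta":
        ses, los, his = _delta_cis(fit, probs, pairs, level)
        method = "gcomp+delta"
    else:
        raise ValueError(f"unknown ci method {ci!r}")

    rows = []
    n_tests = len(pairs)
    for (i, j) in pairs:
        d = diffs[(i, j)]
        se = ses[(i, j)]
        p = 2.0 * norm.sf(abs(d) / se) if se > 0 else (0.0 if d else 1.0)
        if adjust == "bonferroni":
            p = min(1.0, p * n_tests)
        rows.append({"level_a": levels[i], "level_b": levels[j],
                     "estimate_pp": d, "se": se,
                     "ci_low": los[(i, j)], "ci_high": his[(i, j)],
                     "p": p, "reference": levels[0],
                     "method": method + (f"+{adjust}" if adjust != "none" else "")})
    return pd.DataFrame(rows)


def _delta_cis(fit: FitResult, probs, pairs, level):
    group = fit.spec.group
    levels = fit.factor_levels[group]
    beta = fit.params.to_numpy()
    Sigma = fit.cov.to_numpy()
    grads = []
    for lv in levels:
        cf = fit.frame.copy()
        cf[group] = pd.Categorical([lv] * len(cf), categories=levels)
        Xcf = grid_design(fit.design_info, cf)
        mu = expit(Xcf @ beta)
        grads.append((Xcf * (mu * (1 - mu))[:, None]).mean(axis=0))
    z = norm.ppf(0.5 + level / 2.0)
    ses, los, his = {}, {}, {}
    for i, j in pairs:
        g = grads[i] - grads[j]
        se = 100.0 * float(np.sqrt(g @ Sigma @ g))
        d = 100.0 * (probs[i] - probs[j])
        ses[(i, j)], los[(i, j)], his[(i, j)] = se, d - z * se, d + z * se
    return ses, los, his


def _bootstrap_cis(fit: FitResult, pairs, B, seed, level, max_failure_rate):
    rng = np.random.default_rng(seed)
    frame = fit.frame.reset_index(drop=True)
    y = np.asarray(fit.diagnostics["_y"], dtype=float)
    n = len(frame)
    draws = {pair: [] for pair in pairs}
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        fb = frame.iloc[idx].reset_index(drop=True)
        yb = y[idx]
        try:
            Xb, _, _ = design_matrix(fb, fit.spec)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error")
                    res = sm.GLM(yb, Xb, family=sm.families.Binomial()).fit(maxiter=100)
                if (not res.converged) or np.max(np.abs(res.params)) > _SEPARATION_COEF:
                    raise RuntimeError("separation")
                bb = np.asarray(res.params)
            except Exception:
                bb, _ = _ridge_logit(yb, Xb)
            pb = _marginal_probs(bb, fit, fb)
        except Exception:
            failures += 1
            continue
        for i, j in pairs:
            draws[(i, j)].append(100.0 * (pb[i] - pb[j]))
    if failures > max_failure_rate * B:
        raise PainProError(
            f"bootstrap failure rate {failures}/{B} exceeds {max_failure_rate:.0%}")
    alpha = 1.0 - level
    ses, los, his = {}, {}, {}
    for pair in pairs:
        d = np.asarray(draws[pair])
        ses[pair] = float(d.std(ddof=1)) if len(d) > 1 else float("inf")
        los[pair] = float(np.quantile(d, alpha / 2))
        his[pair] = float(np.quantile(d, 1 - alpha / 2))
    return ses, los, his
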