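"""Adjusted analysis of the primary endpoint: beta regression with
estimated marginal means and Tukey-adjusted pairwise contrasts.

The composite score (NRS 0-10) is rescaled into the open unit interval
and modelled with a beta likelihood in mean-precision parameterisation
(logit mean link, constant precision φ).  Group effects are then
summarised as estimated marginal means (EMMs): linear predictors are
averaged on the link scale over an equal-weight reference grid of all
factor covariates, with continuous covariates at their sample means,
back-transformed through the inverse link and the inverse of the
boundary-compression rescaling, so estimates land back on the NRS scale.
All pairwise group differences use the studentized-range (Tukey)
adjustment by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import studentized_range, t as t_dist
from statsmodels.othermod.betareg import BetaModel

from . import scores
from .errors import ConvergenceError, PainProError
from .model_base import (FitResult, ModelSpec, build_frame, check_cells,
                         check_degenerate, design_matrix, grid_design)
from .registry import complete_case_subset


def fit_beta(data: pd.DataFrame, spec: ModelSpec | None = None, *,
             n_effective: int | None = None, income_mode: str = "fixed",
             penalty: float = 2.0) -> FitResult:
    """Fit the beta-outcome model by maximum likelihood on complete cases.

    ``n_effective`` pins the boundary-compression sample size (defaults
    to the number of complete cases).  ``income_mode`` controls the
    income-stratum adjustment: ``"fixed"`` (default) estimates a stratum
    intercept; ``"penalized"`` shrinks the stratum coefficients with an
    L2 penalty of weight ``penalty`` — a random-intercept-style fit that
    stays identified with only two strata.
    """
    spec = spec or ModelSpec()
    cc, cc_report = complete_case_subset(data, spec.variables())
    if len(cc) == 0:
        raise PainProError("no complete cases for the requested model")
    frame, factor_levels, cont_means = build_frame(cc, spec)
    check_degenerate(frame, spec)

    n_used = len(cc)
    n_eff = n_effective or n_used
    y = scores.rescale_to_open_unit(cc[spec.outcome].astype(float).to_numpy(), n_eff)
    X, colnames, design_info = design_matrix(frame, spec)
    p = X.shape[1]

    model = BetaModel(y, X)
    stratum_idx = [j for j, c in enumerate(colnames)
                   if spec.offset_stratum and c.startswith(spec.offset_stratum)]
    if income_mode == "penalized" and stratum_idx:
        res, params_full, cov_full = _fit_penalized(model, p, stratum_idx, penalty)
        method = "beta-ml-penalized-stratum"
        grad_norm = float(np.linalg.norm(res.jac))
        converged = res.success or grad_norm < 1e-3
        if not converged:
            raise ConvergenceError(
                f"penalized beta fit did not converge (gradient norm {grad_norm:.3g})")
    elif income_mode == "fixed":
        sm_res = model.fit(disp=0, maxiter=500)
        converged = bool(sm_res.mle_retvals.get("converged", False))
        grad_norm = float(np.linalg.norm(model.score(sm_res.params)))
        if not converged and grad_norm > 1e-3:
            raise ConvergenceError(
                f"beta fit did not converge (gradient norm {grad_norm:.3g})")
        params_full = sm_res.params
        cov_full = np.asarray(sm_res.cov_params())
        res = sm_res
        method = "beta-ml"
    else:
        raise ValueError(f"unknown income_mode {income_mode!r}")

    phi = float(np.exp(params_full[p]))  # precision uses a log link
    fit = FitResult(
        params=pd.Series(params_full[:p], index=colnames),
        cov=pd.DataFrame(cov_full[:p, :p], index=colnames, columns=colnames),
        phi=phi, link="logit", n_used=n_used, n_effective=n_eff,
        resid_df=n_used - p, spec=spec, design_info=design_info,
        factor_levels=factor_levels, cont_means=cont_means, frame=frame,
        method=method, converged=True,
        diagnostics={"gradient_norm": grad_norm, "complete_case": cc_report,
                     "loglike": float(model.loglike(params_full))},
        sm_result=res,
    )
    return fit


def _fit_penalized(model: BetaModel, p: int, stratum_idx: list[int], penalty: float):
    """L2-penalised ML on the stratum coefficients (ridge random-intercept)."""
    from statsmodels.tools.numdiff import approx_hess

    mask = np.zeros(p + 1)
    mask[stratum_idx] = 1.0

    def negloglike(par):
        return -model.loglike(par) + 0.5 * penalty * np.sum(mask * par ** 2)

    def grad(par):
        return -model.score(par) + penalty * mask * par

    start = np.r_[np.zeros(p), 0.0]
    start[0] = 0.0
    res = optimize.minimize(negloglike, start, jac=grad, method="BFGS",
                            options={"maxiter": 500, "gtol": 1e-6})
    H = approx_hess(res.x, negloglike)
    cov = np.linalg.inv(H)
    return res, res.x, cov


@dataclass
class MarginalMeans:
    """EMMs for one factor (or factor combination) with their L-matrix.

    ``table`` has one row per level: NRS-scale estimate with 95 % CI,
    plus the link-scale linear predictor and its SE.  ``L`` holds the
    averaging vectors so contrasts can reuse the fit covariance.
    """

    table: pd.DataFrame
    L: np.ndarray
    factors: list
    fit: FitResult

    def __len__(self):
        return len(self.table)


def _nrs_from_eta(eta, fit: FitResult):
    return scores.inverse_rescale(expit(np.asarray(eta)), fit.n_effective)


def _dnrs_deta(eta, fit: FitResult):
    mu = expit(np.asarray(eta))
    n = fit.n_effective
    return 10.0 * (n / (n - 1.0)) * mu * (1.0 - mu)


def emmeans(fit: FitResult, factor=None, *, level: float = 0.95) -> MarginalMeans:
    """Estimated marginal means on the NRS scale.

    ``factor`` is a factor name or list of names (default: the group
    factor).  The reference grid crosses all factor levels with equal
    weight and holds continuous covariates at their sample means;
    averaging happens on the link scale, and the inverse link plus
    inverse rescaling map the result back to NRS 0-10.  CIs are delta
    method on the link scale, back-transformed (hence respecting the
    (0, 10) bounds).
    """
    factors = [factor] if isinstance(factor, str) else list(factor or [fit.spec.group])
    for f in factors:
        if f not in fit.factor_levels:
            raise PainProError(f"factor {f!r} is not in the fitted model")
    grid = fit.reference_grid()
    Xg = grid_design(fit.design_info, grid)
    beta = fit.params.to_numpy()
    Sigma = fit.cov.to_numpy()

    level_sets = [fit.factor_levels[f] for f in factors]
    from itertools import product as _product
    rows, Ls = [], []
    tcrit = t_dist.ppf(0.5 + level / 2.0, fit.resid_df)
    for combo in _product(*level_sets):
        mask = np.ones(len(grid), dtype=bool)
        for f, lv in zip(factors, combo):
            mask &= (grid[f] == lv).to_numpy()
        L = Xg[mask].mean(axis=0)
        eta = float(L @ beta)
        se_eta = float(np.sqrt(L @ Sigma @ L))
        est = _nrs_from_eta(eta, fit)
        lo = _nrs_from_eta(eta - tcrit * se_eta, fit)
        hi = _nrs_from_eta(eta + tcrit * se_eta, fit)
        se_resp = abs(_dnrs_deta(eta, fit)) * se_eta
        rows.append({**{f: lv for f, lv in zip(factors, combo)},
                     "estimate": est, "se": se_resp, "ci_low": lo, "ci_high": hi,
                     "eta": eta, "se_eta": se_eta})
        Ls.append(L)
    table = pd.DataFrame(rows)
    return MarginalMeans(table=table, L=np.asarray(Ls), factors=factors, fit=fit)


def pairwise_contrasts(emm: MarginalMeans, adjust: str = "tukey",
                       *, level: float = 0.95) -> pd.DataFrame:
    """All pairwise differences between EMM levels, on the NRS scale.

    The test statistic is formed on the link scale; with
    ``adjust="tukey"`` p-values and simultaneous CIs come from the
    studentized-range distribution with the fit's residual degrees of
    freedom, with ``adjust="none"`` from the t distribution.  Contrasts
    are antisymmetric by construction.
    """
    k = len(emm)
    if k < 2:
        raise PainProError("need at least 2 levels for pairwise contrasts")
    fit = emm.fit
    Sigma = fit.cov.to_numpy()
    df = fit.resid_df
    labels = emm.table[emm.factors].astype(str).agg(" | ".join, axis=1).to_list()
    if adjust == "tukey":
        crit = studentized_range.ppf(level, k, df) / np.sqrt(2.0)
    elif adjust == "none":
        crit = t_dist.ppf(0.5 + level / 2.0, df)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    rows = []
    for i, j in combinations(range(k), 2):
        Ld = emm.L[i] - emm.L[j]
        d_eta = emm.table["eta"][i] - emm.table["eta"][j]
        se_eta = float(np.sqrt(Ld @ Sigma @ Ld))
        if se_eta == 0.0:
            raise PainProError(f"singular contrast covariance for pair "
                               f"({labels[i]}, {labels[j]})")
        tstat = d_eta / se_eta
        if adjust == "tukey":
            pval = float(studentized_range.sf(np.sqrt(2.0) * abs(tstat), k, df))
        else:
            pval = float(2.0 * t_dist.sf(abs(tstat), df))
        # response-scale difference and delta-method SE
        diff = emm.table["estimate"][i] - emm.table["estimate"][j]
        g = (_dnrs_deta(emm.table["eta"][i], fit) * emm.L[i]
             - _dnrs_deta(emm.table["eta"][j], fit) * emm.L[j])
        se_resp = float(np.sqrt(g @ Sigma @ g))
        rows.append({"level_a": labels[i], "level_b": labels[j],
                     "estimate": diff, "se": se_resp,
                     "ci_low": diff - crit * se_resp, "ci_high": diff + crit * se_resp,
                     "t": tstat, "p": min(pval, 1.0), "adjust": adjust})
    return pd.DataFrame(rows)


def emmeans_by_oands(fit: FitResult, oands: str = "oands_flag",
                     adjust: str = "tukey"):
    """EMMs for the subgroup x O&S grid (12 levels) plus pairwise contrasts.

    Requires the subgroup-by-O&S interaction in the fitted model and a
    non-empty cell for every combination.
    """
    group = fit.spec.group
    if (group, oands) not in fit.spec.interactions and \
            (oands, group) not in fit.spec.interactions:
        raise PainProError(
            f"model lacks the {group} x {oands} interaction needed for the O&S split")
    check_cells(fit.frame, group, oands)
    mm = emmeans(fit, [group, oands])
    return mm, pairwise_contrasts(mm, adjust=adjust)
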