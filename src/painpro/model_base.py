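"""Shared machinery for the adjusted models: model specs, design frames, fits.

Both adjusted analyses (beta-outcome PCS model, logistic opioid-use
model) share one covariate set, one patsy-built design, and one
reference-grid convention, so the plumbing lives here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
import patsy

from .errors import PainProError
from .registry import SUBGROUPS

DEFAULT_FACTORS = ["sex", "enrolment_period", "nonopioid_pre_intra", "nonopioid_post",
                   "opioid_pacu", "opioid_ward", "oands_flag"]


@dataclass
class ModelSpec:
    """Covariate specification shared by the adjusted models.

    ``group`` is the factor of primary interest (anesthesia subgroup);
    ``offset_stratum`` is the income stratum entering as a stratum
    intercept; ``interactions`` are pairs of factor names, e.g.
    ``[("subgroup", "oands_flag")]`` for the O&S-split analysis.
    """

    outcome: str = "pcs"
    group: str = "subgroup"
    factors: list = field(default_factory=lambda: list(DEFAULT_FACTORS))
    continuous: list = field(default_factory=lambda: ["age", "weight"])
    offset_stratum: str | None = "country_income"
    interactions: list = field(default_factory=list)

    def with_interaction(self, a: str, b: str) -> "ModelSpec":
        return replace(self, interactions=[*self.interactions, (a, b)])

    def all_factors(self) -> list[str]:
        out = [self.group, *self.factors]
        if self.offset_stratum:
            out.append(self.offset_stratum)
        return out

    def variables(self) -> list[str]:
        return [self.outcome, *self.all_factors(), *self.continuous]

    def rhs_formula(self) -> str:
        terms = list(self.all_factors()) + list(self.continuous)
        terms += [f"{a}:{b}" for a, b in self.interactions]
        return " + ".join(terms) if terms else "1"


def build_frame(data: pd.DataFrame, spec: ModelSpec,
                group_levels: list | None = None):
    """Typed model frame for patsy: ordered categoricals + float covariates.

    Returns ``(frame, factor_levels, cont_means)``.  Factor levels are
    the observed ones, ordered canonically for the anesthesia subgroup
    (publication order) and lexicographically otherwise, so design
    coding is reproducible regardless of row order.
    """
    frame = pd.DataFrame(index=data.index)
    factor_levels: dict[str, list] = {}
    for f in spec.all_factors():
        col = data[f].astype("string").astype(object)
        observed = sorted(set(col.dropna()))
        if f == spec.group:
            canonical = group_levels or SUBGROUPS
            levels = [g for g in canonical if g in observed]
            levels += [g for g in observed if g not in levels]
        else:
            levels = observed
        if len(levels) < 1:
            raise PainProError(f"factor {f!r} has no observed levels")
        frame[f] = pd.Categorical(col, categories=levels)
        factor_levels[f] = levels
    cont_means = {}
    for c in spec.continuous:
        frame[c] = data[c].astype(float)
        cont_means[c] = float(frame[c].mean())
    return frame, factor_levels, cont_means


def check_cells(frame: pd.DataFrame, a: str, b: str) -> None:
    """Raise if any cell of the a x b cross-classification is empty."""
    tab = pd.crosstab(frame[a], frame[b], dropna=False)
    for la in tab.index:
        for lb in tab.columns:
            if tab.loc[la, lb] == 0:
                raise PainProError(f"empty cell in {a} x {b}: ({la}, {lb})")


def check_degenerate(frame: pd.DataFrame, spec: ModelSpec, min_per_level: int = 2) -> None:
    for f in spec.all_factors():
        counts = frame[f].value_counts()
        thin = counts[counts < min_per_level]
        if len(thin):
            raise PainProError(
                f"degenerate stratum: factor {f!r} level(s) "
                f"{list(thin.index)} have fewer than {min_per_level} records")
    for a, b in spec.interactions:
        check_cells(frame, a, b)


def design_matrix(frame: pd.DataFrame, spec: ModelSpec):
    """Build the design matrix; returns ``(X ndarray, column names, design_info)``."""
    dm = patsy.dmatrix("1 + " + spec.rhs_formula(), frame, return_type="dataframe",
                       NA_action="raise")
    return dm.to_numpy(), list(dm.columns), dm.design_info


def grid_design(design_info, grid: pd.DataFrame) -> np.ndarray:
    """Design rows for a reference grid, using the training design coding."""
    (m,) = patsy.build_design_matrices([design_info], grid)
    return np.asarray(m)


@dataclass
class FitResult:
    """A fitted GLM-type model plus everything needed for marginal means.

    ``params``/``cov`` cover the mean model only; ``phi`` is the beta
    precision (``None`` for logistic fits).  ``frame`` retains the
    complete-case model frame so marginalisation (reference grids,
    g-computation, bootstrap) can reconstruct designs exactly.
    """

    params: pd.Series
    cov: pd.DataFrame
    phi: float | None
    link: str
    n_used: int
    n_effective: int | None
    resid_df: int
    spec: ModelSpec
    design_info: object
    factor_levels: dict
    cont_means: dict
    frame: pd.DataFrame
    method: str
    converged: bool
    diagnostics: dict = field(default_factory=dict)
    sm_result: object = None

    def reference_grid(self, extra_cols: dict | None = None) -> pd.DataFrame:
        """Equal-weight grid: all factor-level combinations, continuous at means."""
        names = list(self.factor_levels)
        combos = list(product(*[self.factor_levels[f] for f in names]))
        grid = pd.DataFrame(combos, columns=names)
        for f in names:
            grid[f] = pd.Categorical(grid[f], categories=self.factor_levels[f])
        for c, m in self.cont_means.items():
            grid[c] = m
        if extra_cols:
            for k, v in extra_cols.items():
                grid[k] = v
        return grid
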