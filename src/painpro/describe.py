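"""Unadjusted group summaries and tests (publication-style Tables 1-3).

Continuous and ordinal variables are summarised as median [Q1; Q3] with
quartiles by the linear-interpolation convention (numpy default, R
type 7).  Categorical variables are n (%) on the non-missing
denominator, and every row reports the N it used.  Group comparisons
dispatch to the Mann-Whitney U test (2 groups), the Kruskal-Wallis test
(>2 groups) or the Pearson chi-square test (categorical; Yates
continuity correction on 2x2 tables).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PainProError


def proportion_pct(count: int, total: int) -> float:
    """Percentage on an explicit denominator (used for cohort shares)."""
    if total <= 0:
        raise PainProError("proportion denominator must be positive")
    return 100.0 * count / total


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation quartiles; ignores missing."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise PainProError("no non-missing values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


def group_test(data: pd.DataFrame, variable: str, group: str,
               kind: str, *, anova: bool = False) -> dict:
    """Unadjusted comparison of ``variable`` across the levels of ``group``.

    ``kind`` is ``"continuous"`` (covers ordinal NRS items too) or
    ``"categorical"``.  ``anova=True`` switches continuous variables to a
    one-way analysis of variance instead of the rank test.
    """
    sub = data[[variable, group]].dropna()
    levels = sorted(sub[group].astype(str).unique())
    if len(levels) < 2:
        raise PainProError(f"need >= 2 non-empty groups for {variable!r}")
    if kind == "continuous":
        samples = [sub.loc[sub[group].astype(str) == g, variable].astype(float).to_numpy()
                   for g in levels]
        if any(len(s) == 0 for s in samples):
            raise PainProError("empty group after dropping missing values")
        if anova:
            stat, p = stats.f_oneway(*samples)
            name = "anova"
        elif len(levels) == 2:
            stat, p = stats.mannwhitneyu(*samples, alternative="two-sided")
            name = "mann-whitney-u"
        else:
            stat, p = stats.kruskal(*samples)
            name = "kruskal-wallis"
    elif kind == "categorical":
        tab = pd.crosstab(sub[variable], sub[group])
        correction = tab.shape == (2, 2)
        try:
            stat, p, _, expected = stats.chi2_contingency(tab.to_numpy(),
                                                          correction=correction)
        except ValueError as err:
            raise PainProError(
                f"chi-square not computable for {variable!r} ({err}); "
                "consider merging sparse categories") from err
        if np.any(expected == 0):
            raise PainProError(
                f"zero expected cell count for {variable!r}; merge sparse categories")
        name = "chi-square" + ("-yates" if correction else "")
    else:
        raise ValueError(f"unknown variable kind {kind!r}")
    return {"test": name, "statistic": float(stat), "p": float(p), "n": int(len(sub))}


def summarize(data: pd.DataFrame, variables: dict[str, str], group: str,
              *, tests: bool = True) -> pd.DataFrame:
    """Tidy per-group summary of ``variables`` (name -> kind).

    One row per variable (continuous) or per variable level
    (categorical) and group, with raw numbers; the per-variable test and
    N ride along on every row of that variable.  Percentages within a
    categorical variable sum to 100 up to rounding because they share
    the non-missing denominator.
    """
    if group not in data.columns:
        raise PainProError(f"unknown grouping variable {group!r}")
    glevels = sorted(data[group].dropna().astype(str).unique())
    if not glevels:
        raise PainProError(f"grouping variable {group!r} has no observed levels")
    rows = []
    for var, kind in variables.items():
        if var not in data.columns:
            raise PainProError(f"unknown variable {var!r}")
        sub = data[[var, group]].dropna()
        test = group_test(data, var, group, kind) if tests else None
        for g in glevels:
            vals = sub.loc[sub[group].astype(str) == g, var]
            if len(vals) == 0:
                raise PainProError(f"empty group {g!r} for variable {var!r}")
            if kind == "continuous":
                med, q1, q3 = median_iqr(vals.astype(float))
                rows.append({"variable": var, "level": None, "group": g,
                             "n": len(vals), "median": med, "q1": q1, "q3": q3,
                             "count": None, "pct": None,
                             "display": f"{med:.1f} [{q1:.1f}; {q3:.1f}]",
                             "n_variable": int(len(sub)),
                             "test": test["test"] if test else None,
                             "p": test["p"] if test else None})
            else:
                denom = len(vals)
                for lv, cnt in vals.astype(str).value_counts().sort_index().items():
                    pct = proportion_pct(int(cnt), denom)
                    rows.append({"variable": var, "level": lv, "group": g,
                                 "n": denom, "median": None, "q1": None, "q3": None,
                                 "count": int(cnt), "pct": pct,
                                 "display": f"{int(cnt)} ({pct:.1f}%)",
                                 "n_variable": int(len(sub)),
                                 "test": test["test"] if test else None,
                                 "p": test["p"] if test else None})
    return pd.DataFrame(rows)


def summary_markdown(table: pd.DataFrame, title: str = "Summary") -> str:
    """Render a summarize() table as a compact publication-style Markdown table."""
    lines = [f"### {title}", ""]
    groups = list(dict.fromkeys(table["group"]))
    header = ["Variable"] + groups + ["Test", "P", "N"]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for (var, level), chunk in table.groupby(["variable", "level"], dropna=False,
                                             sort=False):
        name = var if level is None or (isinstance(level, float) and np.isnan(level)) \
            else f"{var} = {level}"
        cells = []
        for g in groups:
            row = chunk[chunk["group"] == g]
            cells.append(row["display"].iloc[0] if len(row) else "")
        p = chunk["p"].iloc[0]
        ptxt = "" if p is None or (isinstance(p, float) and np.isnan(p)) else (
            "<0.001" if p < 0.001 else f"{p:.3f}")
        lines.append("| " + " | ".join(
            [name] + cells + [str(chunk['test'].iloc[0] or ""), ptxt,
                              str(chunk['n_variable'].iloc[0])]) + " |")
    return "\n".join(lines) + "\n"
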