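"""Composite patient-reported-outcome scores and the bounded-outcome rescaling.

The primary endpoint is the pain composite score (PCS), a time-weighted
blend of worst and least pain over the first postoperative day::

    PCS = worst * t + least * (1 - t),   t = fraction of time in severe pain

so the PCS is always a convex combination of the two intensity ratings.
Secondary composites are item means on the same NRS 0-10 scale:
physical-interference total score (PITS), emotional-interference score
(EIS: anxiety, helplessness), adverse-events score (AES), and the global
PRO-Score summarising all four.

For beta-outcome modelling, NRS scores are divided by 10 and compressed
away from the boundaries of [0, 1] so that every value is strictly inside
the open unit interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import registry
from .errors import PainProError


def pcs(worst, least, time_fraction):
    """Pain composite score: ``worst * t + least * (1 - t)``.

    ``time_fraction`` is the proportion of the first 24 h spent in severe
    pain, on [0, 1].  Accepts scalars or arrays; missing inputs propagate.
    """
    worst = np.asarray(worst, dtype=float)
    least = np.asarray(least, dtype=float)
    t = np.asarray(time_fraction, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(t[~np.isnan(t)] > 1.0):
            raise ValueError(
                "time_fraction > 1: time in severe pain must be a proportion "
                "in [0, 1]; divide percentages by 100"
            )
        if np.any(t[~np.isnan(t)] < 0.0):
            raise ValueError("time_fraction must be non-negative")
        for name, v in (("worst", worst), ("least", least)):
            vv = v[~np.isnan(v)]
            if np.any((vv < 0) | (vv > 10)):
                raise ValueError(f"{name} pain must be on the NRS 0-10 scale")
    out = worst * t + least * (1.0 - t)
    return out if out.ndim else float(out)


def item_mean_score(items, min_items: int | None = None):
    """Mean of NRS items, missing-aware.

    ``items`` is a 2-D array/DataFrame (rows = patients, columns = items)
    or a 1-D sequence for a single patient.  The score is the arithmetic
    mean of the non-missing items and is missing when fewer than
    ``min_items`` items are present.  ``min_items=None`` (the default)
    requires every item — strict complete case, consistent with the
    no-imputation policy.
    """
    arr = np.atleast_2d(np.asarray(items, dtype=float))
    if arr.shape[1] == 0:
        raise ValueError("empty item schema")
    if min_items is None:
        min_items = arr.shape[1]
    ok = ~np.isnan(arr)
    vals = np.where(ok, arr, 0.0)
    if np.any((vals < 0) | (vals > 10)):
        raise ValueError("items must be on the NRS 0-10 scale")
    count = ok.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = vals.sum(axis=1) / count
    mean = np.where(count >= max(min_items, 1), mean, np.nan)
    squeezed = np.asarray(items).ndim == 1
    return float(mean[0]) if squeezed else mean


def pro_score(pcs_val, pits, eis, aes):
    """Global PRO-Score: unweighted mean of PCS, PITS, EIS, AES.

    Any missing component makes the PRO-Score missing (complete-case
    propagation).
    """
    stacked = np.column_stack([
        np.atleast_1d(np.asarray(v, dtype=float)) for v in (pcs_val, pits, eis, aes)
    ])
    out = stacked.mean(axis=1)  # np.mean propagates NaN, as required
    return float(out[0]) if np.isscalar(pcs_val) or np.asarray(pcs_val).ndim == 0 else out


def rescale_to_open_unit(values, n_effective: int, strategy: str = "compression",
                         eps: float = 1e-4):
    """Map NRS 0-10 values into the open unit interval for beta modelling.

    Divides by 10, then applies the standard proportion compression
    ``y -> (y * (n - 1) + 0.5) / n`` with ``n`` the effective sample size,
    so boundary values 0 and 10 land strictly inside (0, 1).  The
    alternative ``strategy='epsilon'`` clips to ``[eps, 1 - eps]`` instead.
    """
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((v[~np.isnan(v)] < 0) | (v[~np.isnan(v)] > 10)):
            raise ValueError("values must be on the NRS 0-10 scale")
    y = v / 10.0
    if strategy == "compression":
        if n_effective < 2:
            raise ValueError("n_effective must be >= 2 for boundary compression")
        out = (y * (n_effective - 1) + 0.5) / n_effective
    elif strategy == "epsilon":
        out = np.clip(y, eps, 1.0 - eps)
    else:
        raise ValueError(f"unknown rescale strategy {strategy!r}")
    return out if out.ndim else float(out)


def inverse_rescale(proportions, n_effective: int, strategy: str = "compression"):
    """Invert :func:`rescale_to_open_unit` back to the NRS 0-10 scale.

    For the epsilon strategy the inverse is exact only away from the
    clipped boundary.
    """
    p = np.asarray(proportions, dtype=float)
    if strategy == "compression":
        y = (p * n_effective - 0.5) / (n_effective - 1)
    elif strategy == "epsilon":
        y = p
    else:
        raise ValueError(f"unknown rescale strategy {strategy!r}")
    out = y * 10.0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ItemSchema:
    """Which registry columns feed each composite, and optional PRO weights."""

    pits_items: tuple = tuple(registry.PITS_ITEMS)
    eis_items: tuple = tuple(registry.EIS_ITEMS)
    aes_items: tuple = tuple(registry.AES_ITEMS)
    pro_weights: tuple = (1.0, 1.0, 1.0, 1.0)  # PCS, PITS, EIS, AES
    min_items: int | None = None


DEFAULT_ITEM_SCHEMA = ItemSchema()


def score_registry(records: pd.DataFrame,
                   schema: ItemSchema = DEFAULT_ITEM_SCHEMA) -> pd.DataFrame:
    """Append pcs/pits/eis/aes/pro_score columns to a registry table.

    ``time_severe_pct`` (0-100) is converted to a fraction internally.
    Missing inputs yield missing scores; nothing is imputed.
    """
    missing = [c for c in ("worst_pain", "least_pain", "time_severe_pct")
               if c not in records.columns]
    if missing:
        raise PainProError(f"registry lacks columns required for PCS: {missing}")
    out = records.copy()
    t = out["time_severe_pct"].astype(float).to_numpy() / 100.0
    out["pcs"] = pcs(out["worst_pain"].astype(float).to_numpy(),
                     out["least_pain"].astype(float).to_numpy(), t)

    def _items(cols):
        have = [c for c in cols if c in out.columns]
        if len(have) != len(cols):
            raise PainProError(f"registry lacks item columns: {set(cols) - set(have)}")
        return out[list(cols)].astype(float).to_numpy()

    out["pits"] = item_mean_score(_items(schema.pits_items), schema.min_items)
    out["eis"] = item_mean_score(_items(schema.eis_items), schema.min_items)
    out["aes"] = item_mean_score(_items(schema.aes_items), schema.min_items)

    w = np.asarray(schema.pro_weights, dtype=float)
    comps = np.column_stack([out["pcs"], out["pits"], out["eis"], out["aes"]])
    out["pro_score"] = comps @ (w / w.sum())
    return out
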