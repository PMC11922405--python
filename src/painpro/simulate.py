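"""Synthetic PAIN OUT-style registry generator with known ground truth.

The real registry behind this kind of analysis is not public, so every
downstream stage is exercised on simulated registries whose generating
parameters are known.  The generator draws a latent pain composite score
from a beta distribution in mean-precision form (mean
``logit⁻¹(η)``, precision ``phi``; ``α = μφ``, ``β = (1-μ)φ``) with a
linear predictor built from anesthesia subgroup, preoperative
opioid/substance status (O&S), demographic and treatment covariates, and
an income-stratum offset.  The observable questionnaire triple
(worst pain, least pain, % time in severe pain) is then reverse-engineered
so that the forward PCS formula reproduces the latent score up to the
discretisation imposed by integer NRS ratings and the 10 % time grid.

Defaults (:func:`default_paperlike_config`) reproduce the published
cohort structure: n = 4328, six anesthesia subgroups with the published
mix and an income-dependent composition in which continuous nerve-block
catheters are nearly absent in middle/low-income hospitals, 9.5 % O&S
prevalence, per-subgroup opioid-use probabilities, and right-skewed
lognormal morphine-equivalent doses.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri
from scipy.stats import beta as beta_dist

from .errors import ConfigError
from .registry import SUBGROUPS, ENROLMENT_PERIODS, PITS_ITEMS, EIS_ITEMS, AES_ITEMS

AGE_CENTER = 67.0   # years; linear-predictor centring for age
WEIGHT_CENTER = 80.0  # kg

#: drug mix used for simulated postoperative administrations
_ADMIN_DRUGS = [("morphine", "iv", 3.0), ("morphine", "oral", 1.0),
                ("oxycodone", "oral", 1.5), ("piritramide", "iv", 2.0),
                ("tramadol", "oral", 0.1)]
_ADMIN_PROBS = [0.35, 0.20, 0.20, 0.15, 0.10]

_ITEM_SHAPE = {"interference": 1.8, "emotion": 2.2, "adverse": 2.5}


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic registry.

    ``subgroup_probs`` maps income stratum to a 6-vector over
    :data:`~painpro.registry.SUBGROUPS`; ``pcs_group_effects`` are
    per-subgroup baseline logits of the mean rescaled PCS at reference
    covariate values; ``covariate_effects`` are additive logit-scale
    shifts (age and weight enter per 10 units, centred at 67 y / 80 kg).
    """

    n: int = 4328
    seed: int = 0
    subgroup_probs: dict = field(default_factory=dict)
    income_split: float = 0.748          # share of patients from high-income countries
    oands_prevalence: float = 0.095
    pcs_group_effects: tuple = (-0.575, -0.532, -0.800, -0.847, -0.754, -0.800)
    oands_effect: float = 0.4
    covariate_effects: dict = field(default_factory=dict)
    phi: float = 2.5                     # beta precision of the latent PCS
    opioid_use_probs: tuple = (0.927, 0.992, 0.892, 0.859, 0.995, 0.804)
    me_lognormal: tuple = (2.7, 0.9)     # (meanlog, sdlog) of total 24-h ME among users
    missingness: dict = field(default_factory=dict)
    item_corr: float = 0.6               # Gaussian-copula correlation of items with PCS

    def validate(self) -> None:
        problems = []
        if self.n < 1:
            problems.append(f"n must be >= 1, got {self.n}")
        if not self.phi > 0:
            problems.append(f"phi must be > 0, got {self.phi}")
        for stratum, p in self.subgroup_probs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (6,):
                problems.append(f"subgroup_probs[{stratum}] must have 6 entries")
            elif np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                problems.append(f"subgroup_probs[{stratum}] must be a probability vector")
        for name, v in [("income_split", self.income_split),
                        ("oands_prevalence", self.oands_prevalence),
                        ("item_corr", abs(self.item_corr))]:
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        use = np.asarray(self.opioid_use_probs, dtype=float)
        if use.shape != (6,) or np.any((use < 0) | (use > 1)):
            problems.append("opioid_use_probs must be 6 probabilities in [0, 1]")
        if len(self.pcs_group_effects) != 6:
            problems.append("pcs_group_effects must have 6 entries")
        for k, v in self.missingness.items():
            if not 0.0 <= float(v) <= 1.0:
                problems.append(f"missingness[{k}] must be in [0, 1], got {v}")
        if problems:
            raise ConfigError(problems)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subgroup_probs"] = {k: list(map(float, v)) for k, v in self.subgroup_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError([f"unknown simulation config key: {k}" for k in sorted(unknown)])
        cfg = cls(**{k: (tuple(v) if isinstance(getattr(cls, "__dataclass_fields__")[k].default,
                                               tuple) and isinstance(v, list) else v)
                     for k, v in d.items()})
        return cfg


@dataclass
class GroundTruth:
    """Generator-side targets for parameter-recovery checks."""

    true_emm: np.ndarray          # 6-vector, NRS scale, equal-weight covariate grid
    true_emm_by_oands: np.ndarray  # (6, 2): columns O&S no / yes
    true_use_probs: np.ndarray
    config: dict

    def to_json(self, path) -> None:
        doc = {"true_emm": list(map(float, self.true_emm)),
               "true_emm_by_oands": [list(map(float, r)) for r in self.true_emm_by_oands],
               "true_use_probs": list(map(float, self.true_use_probs)),
               "subgroups": SUBGROUPS,
               "config": self.config}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


def _default_covariate_effects() -> dict:
    return {
        "sex_male": -0.05,
        "age_per10": 0.03,
        "weight_per10": 0.02,
        "period_P2013_2017": -0.05,
        "period_P2017_2020": -0.10,
        "nonopioid_pre_intra": -0.05,
        "nonopioid_post": -0.05,
        "opioid_pacu": 0.10,
        "opioid_ward": 0.10,
        "income_middle_low": 0.10,
    }


def default_paperlike_config(n: int = 4328, seed: int = 0) -> SimulationConfig:
    """Configuration emulating the published cohort structure.

    Subgroup-by-income composition and opioid-use probabilities follow
    the published subgroup counts; the marginal subgroup mix works out to
    roughly (0.136, 0.182, 0.130, 0.243, 0.128, 0.180) over
    (GA-o, GA&PNBc, GA&PNBs, SA-o, SA&PNBc, SA&PNBs).
    """
    high = np.array([415, 750, 340, 705, 492, 535], dtype=float)
    mid_low = np.array([174, 39, 223, 346, 64, 245], dtype=float)
    cfg = SimulationConfig(
        n=n,
        seed=seed,
        subgroup_probs={"high": tuple(high / high.sum()),
                        "middle_low": tuple(mid_low / mid_low.sum())},
        income_split=float(high.sum() / (high.sum() + mid_low.sum())),
        oands_prevalence=0.095,
        covariate_effects=_default_covariate_effects(),
        missingness={
            "sex": 0.002, "preexisting_pain": 0.03, "preexisting_pain_location": 0.15,
            "satisfaction": 0.05, "allowed_participate": 0.08, "pain_relief_pct": 0.08,
            "desire_more_treatment": 0.04,
            **{c: 0.01 for c in PITS_ITEMS + EIS_ITEMS + AES_ITEMS},
        },
    )
    cfg.validate()
    return cfg


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: stable under reordering of the generation code."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def linear_predictor(config: SimulationConfig, subgroup_idx, *, sex_male, age, weight,
                     period, oands, nonop_pre, nonop_post, opioid_pacu, opioid_ward,
                     income_midlow):
    """Logit-scale mean of the rescaled latent PCS for given covariates."""
    ce = dict.fromkeys(_default_covariate_effects(), 0.0)
    ce.update(config.covariate_effects)  # unspecified effects are zero
    eff = np.asarray(config.pcs_group_effects, dtype=float)
    eta = eff[np.asarray(subgroup_idx)]
    eta = eta + config.oands_effect * np.asarray(oands, dtype=float)
    eta = eta + ce["sex_male"] * np.asarray(sex_male, dtype=float)
    eta = eta + ce["age_per10"] * (np.asarray(age, dtype=float) - AGE_CENTER) / 10.0
    eta = eta + ce["weight_per10"] * (np.asarray(weight, dtype=float) - WEIGHT_CENTER) / 10.0
    period = np.asarray(period)
    eta = eta + ce["period_P2013_2017"] * (period == 1)
    eta = eta + ce["period_P2017_2020"] * (period == 2)
    eta = eta + ce["nonopioid_pre_intra"] * np.asarray(nonop_pre, dtype=float)
    eta = eta + ce["nonopioid_post"] * np.asarray(nonop_post, dtype=float)
    eta = eta + ce["opioid_pacu"] * np.asarray(opioid_pacu, dtype=float)
    eta = eta + ce["opioid_ward"] * np.asarray(opioid_ward, dtype=float)
    eta = eta + ce["income_middle_low"] * np.asarray(income_midlow, dtype=float)
    return eta


def _true_emm(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth marginal means on the NRS scale.

    Averages the response-scale mean over an equal-weight grid of all
    factor covariates with age/weight at their centres — the same
    reference-grid semantics the estimated marginal means use.
    """
    from itertools import product

    grid = list(product([0, 1], [0, 1, 2], [0, 1], [0, 1], [0, 1], [0, 1], [0, 1], [0, 1]))
    # columns: sex_male, period, nonop_pre, nonop_post, pacu, ward, income, oands
    g = np.array(grid, dtype=float)
    emm = np.zeros(6)
    emm_by = np.zeros((6, 2))
    for k in range(6):
        eta = linear_predictor(
            config, np.full(len(g), k, dtype=int),
            sex_male=g[:, 0], age=AGE_CENTER, weight=WEIGHT_CENTER, period=g[:, 1],
            oands=g[:, 7], nonop_pre=g[:, 2], nonop_post=g[:, 3],
            opioid_pacu=g[:, 4], opioid_ward=g[:, 5], income_midlow=g[:, 6],
        )
        mu = expit(eta)
        emm[k] = 10.0 * mu.mean()
        for o in (0, 1):
            emm_by[k, o] = 10.0 * mu[g[:, 7] == o].mean()
    return emm, emm_by


def _reverse_engineer_pcs(p: np.ndarray, rng: np.random.Generator):
    """Back out (worst, least, time) whose forward PCS reproduces ``p``.

    Draws a uniform compatible integer pair ``least <= p <= worst`` and
    solves for the time fraction, snapped to the 10 % questionnaire grid;
    the degenerate ``worst == least`` case takes time 0.  The
    discretisation error of the recovered PCS is bounded by
    ``0.05 * (worst - least) <= 0.5`` NRS.

    The latent score is strictly interior (beta-distributed), so a
    snapped triple is never allowed to collapse onto an exact 0 or 10 —
    that would put observable mass on boundary values the latent model
    family excludes, and the analysis pipeline's boundary compression
    would map such artifacts to extreme logits.  Collapsed triples are
    re-expressed as the nearest achievable interior reconstruction: at
    the bottom, worst = round(10 p) (at least 1), least = 0, time = 10 %,
    so a latent 0.34 becomes the plausible low-pain answer
    (worst 3, least 0, 10 % of the time) instead of an exact zero.
    """
    lo = np.floor(p).astype(int)
    hi = np.ceil(p).astype(int)
    least = rng.integers(0, lo + 1)
    worst = rng.integers(hi, 11)
    span = worst - least
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(span > 0, (p - least) / np.where(span > 0, span, 1), 0.0)
    t_snapped = np.round(t * 10.0) / 10.0
    rec = worst * t_snapped + least * (1.0 - t_snapped)
    fix0 = rec <= 0
    worst = np.where(fix0, np.maximum(1, np.round(10.0 * p)).astype(int), worst)
    least = np.where(fix0, 0, least)
    t_snapped = np.where(fix0, 0.1, t_snapped)
    fix10 = rec >= 10
    least = np.where(fix10, np.clip(np.round(10.0 * (p - 9.0)), 0, 9).astype(int), least)
    worst = np.where(fix10, 10, worst)
    t_snapped = np.where(fix10, 0.9, t_snapped)
    return worst, least, t_snapped


def generate(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic registry.

    Returns ``(records, administrations, truth)``; fully reproducible
    from ``config.seed``.
    """
    config.validate()
    n, seed = config.n, config.seed

    income_midlow = (_rng(seed, "income").random(n) >= config.income_split).astype(int)
    subgroup_idx = np.empty(n, dtype=int)
    rng_sub = _rng(seed, "subgroup")
    for s, stratum in ((0, "high"), (1, "middle_low")):
        mask = income_midlow == s
        probs = np.asarray(config.subgroup_probs.get(
            stratum, np.full(6, 1 / 6.0)), dtype=float)
        subgroup_idx[mask] = rng_sub.choice(6, size=int(mask.sum()), p=probs)

    rng_cov = _rng(seed, "covariates")
    sex_male = (rng_cov.random(n) < 0.36).astype(int)
    age = np.clip(np.round(rng_cov.normal(AGE_CENTER, 9.5, n)), 18, 95).astype(int)
    weight = np.clip(np.round(rng_cov.normal(WEIGHT_CENTER, 15.0, n), 1), 40.0, 180.0)
    period = rng_cov.choice(3, size=n, p=[0.25, 0.45, 0.30])
    preexisting = rng_cov.random(n) < 0.888
    pre_intensity = np.where(
        preexisting, np.clip(np.round(rng_cov.normal(7.0, 1.8, n)), 0, 10), np.nan)
    pre_location = np.where(
        preexisting,
        rng_cov.choice(["site_of_surgery", "elsewhere", "both"], size=n, p=[0.70, 0.025, 0.275]),
        None)
    nonop_pre = (rng_cov.random(n) < 0.55).astype(int)
    nonop_post = (rng_cov.random(n) < 0.93).astype(int)

    oands = (_rng(seed, "oands").random(n) < config.oands_prevalence).astype(int)
    preop_me = np.where(
        oands, np.round(np.exp(_rng(seed, "preop_me").normal(3.4, 0.6, n)), 1), np.nan)

    rng_use = _rng(seed, "opioid_use")
    use_p = np.asarray(config.opioid_use_probs, dtype=float)[subgroup_idx]
    use = rng_use.random(n) < use_p
    pacu = use & (rng_use.random(n) < 0.55)
    ward = use & (rng_use.random(n) < 0.90)
    ward = ward | (use & ~pacu)  # every user has at least one location

    eta = linear_predictor(
        config, subgroup_idx, sex_male=sex_male, age=age, weight=weight, period=period,
        oands=oands, nonop_pre=nonop_pre, nonop_post=nonop_post,
        opioid_pacu=pacu.astype(int), opioid_ward=ward.astype(int),
        income_midlow=income_midlow)
    mu = expit(eta)
    a, b = mu * config.phi, (1.0 - mu) * config.phi
    u_latent = _rng(seed, "pcs_latent").random(n)
    pcs_unit = beta_dist.ppf(u_latent, a, b)
    pcs_latent = 10.0 * pcs_unit

    worst, least, t = _reverse_engineer_pcs(pcs_latent, _rng(seed, "pcs_components"))

    # Secondary items: thresholded Gaussian copula tied to the latent PCS
    # through its probability-integral transform.
    z0 = ndtri(np.clip(u_latent, 1e-12, 1 - 1e-12))
    rho = config.item_corr
    rng_items = _rng(seed, "items")

    def _ordinal_items(cols: list[str], shape: float) -> dict:
        out = {}
        for c in cols:
            z = rho * z0 + np.sqrt(1 - rho ** 2) * rng_items.standard_normal(n)
            u = ndtr(z)
            out[c] = np.round(10.0 * u ** shape).astype(int)
        return out

    items = {}
    items.update(_ordinal_items(PITS_ITEMS, _ITEM_SHAPE["interference"]))
    items.update(_ordinal_items(EIS_ITEMS, _ITEM_SHAPE["emotion"]))
    items.update(_ordinal_items(AES_ITEMS, _ITEM_SHAPE["adverse"]))

    rng_care = _rng(seed, "care")
    desire_more = rng_care.random(n) < 0.22
    satisfaction = np.clip(np.round(rng_care.normal(8.5, 1.6, n)), 0, 10).astype(int)
    allowed = np.clip(np.round(rng_care.normal(7.3, 2.8, n)), 0, 10).astype(int)
    pain_relief = np.clip(np.round(rng_care.normal(6.8, 2.2, n)) * 10, 0, 100)

    subgroup = np.array(SUBGROUPS, dtype=object)[subgroup_idx]
    primary = np.where(np.char.startswith(subgroup.astype(str), "GA"), "GA", "SA")
    mode = np.select(
        [np.char.endswith(subgroup.astype(str), "-o"),
         np.char.endswith(subgroup.astype(str), "PNBs")],
        ["none", "single"], default="continuous")
    rng_site = _rng(seed, "pnb_site")
    site = np.where(mode == "none", None,
                    rng_site.choice(["femoral", "adductor_canal", "sciatic", "combination"],
                                    size=n, p=[0.5, 0.25, 0.1, 0.15]))

    records = pd.DataFrame({
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "sex": np.where(sex_male == 1, "male", "female"),
        "age": age,
        "weight": weight,
        "anesthesia_primary": primary,
        "pnb_mode": mode,
        "pnb_site": site,
        "country_income": np.where(income_midlow == 1, "middle_low", "high"),
        "enrolment_period": np.array(ENROLMENT_PERIODS, dtype=object)[period],
        "preexisting_pain": preexisting,
        "preexisting_pain_intensity": pre_intensity,
        "preexisting_pain_location": pre_location,
        "oands_flag": oands.astype(bool),
        "preop_me_mg": preop_me,
        "worst_pain": worst,
        "least_pain": least,
        "time_severe_pct": (t * 100).round(0),
        **items,
        "nonopioid_pre_intra": nonop_pre.astype(bool),
        "nonopioid_post": nonop_post.astype(bool),
        "opioid_pacu": pacu,
        "opioid_ward": ward,
        "desire_more_treatment": desire_more,
        "satisfaction": satisfaction,
        "allowed_participate": allowed,
        "pain_relief_pct": pain_relief,
    })

    administrations = _draw_administrations(records["patient_id"].to_numpy(), use,
                                            config, seed)

    rng_miss = _rng(seed, "missingness")
    for col, p_miss in sorted(config.missingness.items()):
        if col not in records.columns or p_miss <= 0:
            continue
        mask = rng_miss.random(n) < float(p_miss)
        if records[col].dtype == bool:
            records[col] = records[col].astype("boolean")
        records.loc[mask, col] = pd.NA

    emm, emm_by = _true_emm(config)
    truth = GroundTruth(true_emm=emm, true_emm_by_oands=emm_by,
                        true_use_probs=np.asarray(config.opioid_use_probs, dtype=float),
                        config=config.to_dict())
    return records, administrations, truth


def _draw_administrations(patient_ids, use, config, seed) -> pd.DataFrame:
    """Split each user's lognormal total ME across 1-3 administrations."""
    rng = _rng(seed, "administrations")
    meanlog, sdlog = config.me_lognormal
    rows = []
    users = np.flatnonzero(use)
    totals = np.exp(rng.normal(meanlog, sdlog, len(users)))
    n_adm = rng.integers(1, 4, len(users))
    drug_idx = [rng.choice(len(_ADMIN_DRUGS), size=k, p=_ADMIN_PROBS) for k in n_adm]
    for i, pidx in enumerate(users):
        shares = rng.dirichlet(np.ones(n_adm[i]))
        for j in range(n_adm[i]):
            drug, route, factor = _ADMIN_DRUGS[drug_idx[i][j]]
            dose = max(0.1, round(float(totals[i] * shares[j] / factor), 2))
            rows.append((patient_ids[pidx], drug, route, dose))
    return pd.DataFrame(rows, columns=["patient_id", "drug", "route", "dose_mg"])
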