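"""Morphine-equivalent (ME) conversion and opioid-use endpoints.

"Standard" opioid conversion factors differ between references, so the
table used is always explicit and versioned: every report that quotes an
ME carries the table version.  Factors express mg of *oral morphine* per
mg of drug by the given route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConversionTable:
    """Map (drug, route) -> oral-morphine-equivalent factor.

    Subcutaneous administrations fall back to the intravenous factor
    unless an explicit ``(drug, "sc")`` entry overrides this — common ME
    practice for the opioids involved.
    """

    entries: dict = field(default_factory=dict)
    version: str = "unversioned"
    sc_as_iv: bool = True

    def __post_init__(self):
        bad = {k: v for k, v in self.entries.items() if not v > 0}
        if bad:
            raise ValueError(f"conversion factors must be positive: {bad}")
        if self.entries.get(("morphine", "oral"), 1.0) != 1.0:
            raise ValueError("the (morphine, oral) factor must be exactly 1")

    def factor(self, drug: str, route: str) -> float | None:
        """Return the factor, or None for an unknown (drug, route) pair."""
        drug = str(drug).lower()
        route = str(route).lower()
        f = self.entries.get((drug, route))
        if f is None and route == "sc" and self.sc_as_iv:
            f = self.entries.get((drug, "iv"))
        return f

    @classmethod
    def from_yaml(cls, path) -> "ConversionTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        entries = {(str(e["drug"]).lower(), str(e["route"]).lower()): float(e["factor"])
                   for e in doc["entries"]}
        return cls(entries=entries, version=str(doc.get("version", "unversioned")),
                   sc_as_iv=bool(doc.get("sc_as_iv", True)))

    def to_yaml(self, path) -> None:
        doc = {
            "version": self.version,
            "sc_as_iv": self.sc_as_iv,
            "entries": [{"drug": d, "route": r, "factor": f}
                        for (d, r), f in sorted(self.entries.items())],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


#: Default table.  iv morphine 3x oral; piritramide chained through its
#: iv-morphine equivalence (0.7 mg iv morphine per mg -> 2.0 oral);
#: fentanyl factor is per *milligram* (300 oral-morphine mg / mg).
DEFAULT_TABLE = ConversionTable(
    entries={
        ("morphine", "oral"): 1.0,
        ("morphine", "iv"): 3.0,
        ("oxycodone", "oral"): 1.5,
        ("piritramide", "iv"): 2.0,
        ("tramadol", "oral"): 0.1,
        ("tapentadol", "oral"): 0.3,
        ("fentanyl", "iv"): 300.0,
        ("hydromorphone", "oral"): 5.0,
    },
    version="painpro-default-1.0",
)


def to_me(drug: str, route: str, dose_mg: float,
          table: ConversionTable = DEFAULT_TABLE) -> float:
    """Convert one administration to mg oral morphine equivalent.

    Unknown (drug, route) pairs return NaN and are logged — never silently
    zero, since zero would understate consumption.
    """
    if dose_mg < 0:
        raise ValueError(f"negative dose: {dose_mg}")
    f = table.factor(drug, route)
    if f is None:
        log.warning("no conversion factor for (%s, %s); ME set to missing", drug, route)
        return float("nan")
    return float(dose_mg) * f


def me_24h(administrations: pd.DataFrame, patient_ids,
           table: ConversionTable = DEFAULT_TABLE) -> pd.Series:
    """Total first-24-h ME per patient, indexed by ``patient_ids``.

    Patients with no administrations get 0; a patient with *any*
    unconvertible administration gets a missing total (complete-case
    propagation rather than a known-wrong partial sum).
    """
    ids = pd.Index(patient_ids, name="patient_id")
    if len(administrations) == 0:
        return pd.Series(0.0, index=ids, name="me_24h")
    adm = administrations.copy()
    if (adm["dose_mg"] < 0).any():
        raise ValueError("negative dose in administrations table")
    adm["me"] = [
        to_me(d, r, x, table) if pd.notna(x) else np.nan
        for d, r, x in zip(adm["drug"], adm["route"], adm["dose_mg"])
    ]
    # min_count=0 makes the empty group 0; NaN within a group poisons the sum
    totals = adm.groupby("patient_id")["me"].apply(
        lambda s: s.sum() if not s.isna().any() else np.nan
    )
    out = totals.reindex(ids).fillna(0.0)
    # patients present in adm but with NaN totals must stay NaN
    poisoned = totals[totals.isna()].index
    out[out.index.isin(poisoned)] = np.nan
    out.name = "me_24h"
    return out


def opioid_use_flag(records: pd.DataFrame,
                    administrations: pd.DataFrame | None = None) -> pd.Series:
    """Dichotomous opioid use: any postoperative opioid administration (PACU or ward).

    Event-based, not dose-based: a recorded zero-dose administration still
    counts as use.  Missing PACU/ward flags count as no evidence, not as
    missing — the endpoint is 'any record of use'.
    """
    pacu = records.get("opioid_pacu", pd.Series(False, index=records.index))
    ward = records.get("opioid_ward", pd.Series(False, index=records.index))
    flag = pacu.fillna(False).astype(bool) | ward.fillna(False).astype(bool)
    if administrations is not None and len(administrations):
        has_adm = records["patient_id"].isin(administrations["patient_id"].unique())
        flag = flag | has_adm
    flag.name = "opioid_use"
    return flag
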