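"""Registry data model: data dictionary, CSV I/O, filtering, subgroup allocation.

A registry is held as a :class:`pandas.DataFrame` with one row per patient,
typed according to :data:`DATA_DICTIONARY`, plus a companion long-format
table of postoperative analgesic administrations (``patient_id``, ``drug``,
``route``, ``dose_mg``).  Missing values are ``NaN``/``NA`` throughout; no
imputation happens anywhere in the package — downstream analyses are
complete-case.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

log = logging.getLogger(__name__)

# Display order of the six anesthesia subgroups used in every table and model.
SUBGROUPS = ["GA-o", "GA&PNBc", "GA&PNBs", "SA-o", "SA&PNBc", "SA&PNBs"]

EXCLUDED_FAILED_SA = "excluded:failed_SA"
EXCLUDED_EPIDURAL = "excluded:epidural"
EXCLUDED_INCOMPLETE = "excluded:incomplete_anesthesia"
EXCLUSION_TOKENS = [EXCLUDED_FAILED_SA, EXCLUDED_EPIDURAL, EXCLUDED_INCOMPLETE]

ANESTHESIA_PRIMARY = ["GA", "SA", "GA+SA", "GA+epidural"]
PNB_MODES = ["none", "single", "continuous"]
PNB_SITES = ["femoral", "adductor_canal", "sciatic", "combination"]
INCOME_STRATA = ["high", "middle_low"]
ENROLMENT_PERIODS = ["P2010_2012", "P2013_2017", "P2017_2020"]
PAIN_LOCATIONS = ["site_of_surgery", "elsewhere", "both"]
ROUTES = ["oral", "iv", "sc", "other"]

# Default item columns feeding the secondary composite scores.  The
# physical-interference block (PITS) uses three items, emotional
# interference (EIS) two, pain-related adverse events (AES) four.
PITS_ITEMS = ["interference_activity", "interference_breathing", "interference_sleep"]
EIS_ITEMS = ["emotion_anxiety", "emotion_helplessness"]
AES_ITEMS = ["adverse_nausea", "adverse_drowsiness", "adverse_itching", "adverse_dizziness"]


@dataclass(frozen=True)
class ColumnSpec:
    """One entry of the registry data dictionary."""

    kind: str  # "str" | "int" | "float" | "bool" | "cat"
    allowed: tuple | None = None
    lo: float | None = None
    hi: float | None = None
    mandatory: bool = False


def _nrs(mandatory=False) -> ColumnSpec:
    return ColumnSpec("int", lo=0, hi=10, mandatory=mandatory)


DATA_DICTIONARY: dict[str, ColumnSpec] = {
    "patient_id": ColumnSpec("str", mandatory=True),
    "sex": ColumnSpec("cat", allowed=("female", "male")),
    "age": ColumnSpec("int", lo=0, hi=130),
    "weight": ColumnSpec("float", lo=0, hi=400),
    "anesthesia_primary": ColumnSpec("cat", allowed=tuple(ANESTHESIA_PRIMARY), mandatory=True),
    "pnb_mode": ColumnSpec("cat", allowed=tuple(PNB_MODES), mandatory=True),
    "pnb_site": ColumnSpec("cat", allowed=tuple(PNB_SITES)),
    "country_income": ColumnSpec("cat", allowed=tuple(INCOME_STRATA)),
    "enrolment_period": ColumnSpec("cat", allowed=tuple(ENROLMENT_PERIODS)),
    "preexisting_pain": ColumnSpec("bool"),
    "preexisting_pain_intensity": _nrs(),
    "preexisting_pain_location": ColumnSpec("cat", allowed=tuple(PAIN_LOCATIONS)),
    "oands_flag": ColumnSpec("bool"),
    "preop_me_mg": ColumnSpec("float", lo=0, hi=10000),
    "worst_pain": _nrs(mandatory=True),
    "least_pain": _nrs(mandatory=True),
    "time_severe_pct": ColumnSpec("float", lo=0, hi=100, mandatory=True),
    **{c: _nrs() for c in PITS_ITEMS},
    **{c: _nrs() for c in EIS_ITEMS},
    **{c: _nrs() for c in AES_ITEMS},
    "nonopioid_pre_intra": ColumnSpec("bool"),
    "nonopioid_post": ColumnSpec("bool"),
    "opioid_pacu": ColumnSpec("bool"),
    "opioid_ward": ColumnSpec("bool"),
    "desire_more_treatment": ColumnSpec("bool"),
    "satisfaction": _nrs(),
    "allowed_participate": _nrs(),
    "pain_relief_pct": ColumnSpec("float", lo=0, hi=100),
    # derived by allocate_subgroup; accepted on re-ingest so filtered output
    # round-trips through the CLI stages
    "subgroup": ColumnSpec("cat", allowed=tuple(SUBGROUPS)),
}

ADMIN_COLUMNS = ["patient_id", "drug", "route", "dose_mg"]

_TRUE = {"true", "t", "yes", "y", "1", "1.0"}
_FALSE = {"false", "f", "no", "n", "0", "0.0"}


def _parse_column(raw: pd.Series, spec: ColumnSpec) -> tuple[pd.Series, int]:
    """Coerce a raw string column to its typed form.

    Returns the typed series and the number of non-empty cells that could
    not be parsed (these become missing, never silently coerced to a
    default).
    """
    s = raw.astype("string").str.strip()
    # empty cell or NA marks missing; "none" stays a real value (pnb_mode)
    s = s.where(~s.str.upper().isin(["", "NA", "NAN"]), other=pd.NA)
    present = s.notna()
    if spec.kind == "str":
        return s, 0
    if spec.kind == "cat":
        ok = s.isin(spec.allowed)
        out = s.where(ok, other=pd.NA)
        return out, int((present & ~ok).sum())
    if spec.kind == "bool":
        low = s.str.lower()
        out = pd.Series(pd.NA, index=s.index, dtype="boolean")
        out[low.isin(_TRUE)] = True
        out[low.isin(_FALSE)] = False
        return out, int((present & out.isna()).sum())
    # numeric kinds
    num = pd.to_numeric(s, errors="coerce")
    bad = present & num.isna()
    if spec.kind == "int":
        frac = num.notna() & (num != np.floor(num))
        bad = bad | frac
        num = num.where(~frac)
    if spec.lo is not None:
        oob = num.notna() & ((num < spec.lo) | (num > spec.hi))
        bad = bad | oob
        num = num.where(~oob)
    out = num.astype("Int64" if spec.kind == "int" else "Float64")
    return out, int(bad.sum())


def read_registry(
    path,
    administrations_path=None,
    dictionary: dict[str, ColumnSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Read a registry CSV (and optional administrations CSV) into typed tables.

    Unknown columns are ignored with a warning; unparseable cells become
    missing and are counted in the returned report.  Raises
    :class:`SchemaError` if a mandatory column is absent.

    Returns ``(records, administrations, report)`` where ``report`` has the
    row count, per-column parse-failure counts and per-column missingness.
    """
    dictionary = dictionary or DATA_DICTIONARY
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_mandatory = [
        c for c, spec in dictionary.items() if spec.mandatory and c not in raw.columns
    ]
    if missing_mandatory:
        raise SchemaError(f"mandatory columns missing from {path}: {missing_mandatory}")
    unknown = [c for c in raw.columns if c not in dictionary]
    if unknown:
        warnings.warn(f"ignoring unknown registry columns: {unknown}", stacklevel=2)

    out = {}
    parse_failures = {}
    for col in dictionary:
        if col not in raw.columns:
            continue
        out[col], nbad = _parse_column(raw[col], dictionary[col])
        if nbad:
            parse_failures[col] = nbad
            warnings.warn(f"column {col!r}: {nbad} unparseable value(s) set to missing",
                          stacklevel=2)
    records = pd.DataFrame(out)

    if administrations_path is not None:
        admin = pd.read_csv(administrations_path, dtype=str, keep_default_na=False)
        miss = [c for c in ADMIN_COLUMNS if c not in admin.columns]
        if miss:
            raise SchemaError(f"administrations file missing columns: {miss}")
        admin = admin[ADMIN_COLUMNS].copy()
        admin["dose_mg"] = pd.to_numeric(admin["dose_mg"], errors="coerce")
        admin["route"] = admin["route"].where(admin["route"].isin(ROUTES))
    else:
        admin = pd.DataFrame(columns=ADMIN_COLUMNS)

    report = {
        "n_rows": len(records),
        "n_administrations": len(admin),
        "parse_failures": parse_failures,
        "missingness": {c: int(records[c].isna().sum()) for c in records.columns},
    }
    log.info("read %d registry rows, %d administrations", len(records), len(admin))
    return records, admin, report


def allocate_subgroup(records: pd.DataFrame) -> pd.Series:
    """Map (anesthesia_primary, pnb_mode) to one of the six anesthesia subgroups.

    Combined spinal+general anesthesia is interpreted as failed spinal
    anesthesia and excluded; combined general+epidural anesthesia is
    excluded because depth of sedation cannot be established.  Exclusion
    reasons are assigned first-match in the order failed-SA, epidural,
    incomplete so the audit trail is deterministic.  Returns a series of
    subgroup labels or ``excluded:*`` tokens aligned with ``records``.
    """
    prim = records["anesthesia_primary"]
    mode = records["pnb_mode"]
    out = pd.Series(pd.NA, index=records.index, dtype="string")
    out[prim == "GA+SA"] = EXCLUDED_FAILED_SA
    out[(prim == "GA+epidural") & out.isna()] = EXCLUDED_EPIDURAL
    undecided = out.isna()
    incomplete = undecided & (prim.isna() | mode.isna())
    out[incomplete] = EXCLUDED_INCOMPLETE
    suffix = mode.map({"none": "-o", "single": "&PNBs", "continuous": "&PNBc"})
    plain = out.isna()
    out[plain] = prim[plain].astype("string") + suffix[plain].astype("string")
    return out


@dataclass
class DoseBounds:
    """Per-drug plausibility bounds (mg) for single administrations.

    The shipped defaults are deliberately permissive: they exist to catch
    data-entry errors (e.g. microgram values keyed as milligrams), not to
    police clinical practice.
    """

    default: tuple[float, float] = (0.0, 5000.0)
    per_drug: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "morphine": (0.0, 1000.0),
        "oxycodone": (0.0, 1000.0),
        "piritramide": (0.0, 500.0),
        "tramadol": (0.0, 2000.0),
        "tapentadol": (0.0, 2000.0),
        "hydromorphone": (0.0, 200.0),
        "fentanyl": (0.0, 10.0),
    })

    def bounds_for(self, drug: str) -> tuple[float, float]:
        return self.per_drug.get(str(drug).lower(), self.default)


def plausibility_filter(
    records: pd.DataFrame,
    administrations: pd.DataFrame | None = None,
    dose_bounds: DoseBounds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Apply the entry plausibility rules.

    Patients younger than 18 years or lighter than 34 kg are removed
    (boundaries inclusive: age 18 and weight 34 are kept).  Administrations
    with doses outside the per-drug plausibility range are dropped while
    the patient record is kept.  Missing age/weight do not exclude — they
    fall to the complete-case step of whichever analysis needs them.

    Returns ``(kept records, kept administrations, exclusion log)``.  The
    log counts satisfy ``kept + sum(excluded) == input`` for both tables.
    """
    dose_bounds = dose_bounds or DoseBounds()
    age_bad = records["age"].notna() & (records["age"] < 18)
    wt_bad = records["weight"].notna() & (records["weight"] < 34)
    reason = pd.Series(pd.NA, index=records.index, dtype="string")
    reason[wt_bad] = "weight<34"
    reason[age_bad] = "age<18"  # age takes precedence when both fail
    kept = records[reason.isna()].copy()

    exclusion_log = {
        "records_in": len(records),
        "records_kept": len(kept),
        "excluded": {
            "age<18": int((reason == "age<18").sum()),
            "weight<34": int((reason == "weight<34").sum()),
        },
    }

    if administrations is None or len(administrations) == 0:
        admin_kept = pd.DataFrame(columns=ADMIN_COLUMNS)
        exclusion_log["administrations_dropped"] = 0
        return kept, admin_kept, exclusion_log

    admin = administrations[administrations["patient_id"].isin(kept["patient_id"])].copy()
    n_orphaned = len(administrations) - len(admin)
    lo = admin["drug"].map(lambda d: dose_bounds.bounds_for(d)[0])
    hi = admin["drug"].map(lambda d: dose_bounds.bounds_for(d)[1])
    ok = admin["dose_mg"].notna() & (admin["dose_mg"] >= lo) & (admin["dose_mg"] <= hi)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d implausible administrations", n_dropped)
    exclusion_log["administrations_dropped"] = n_dropped
    exclusion_log["administrations_of_excluded_patients"] = n_orphaned
    return kept, admin[ok].copy(), exclusion_log


def complete_case_subset(
    records: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, dict]:
    """Retain only records with every listed variable non-missing.

    Returns the subset plus a per-variable missingness report.  Unknown
    variable names raise ``KeyError`` rather than being ignored.
    """
    unknown = [v for v in variables if v not in records.columns]
    if unknown:
        raise KeyError(f"unknown variables for complete-case subset: {unknown}")
    if not variables:
        return records.copy(), {"n_in": len(records), "n_kept": len(records),
                                "missing_per_variable": {}}
    mask = np.ones(len(records), dtype=bool)
    miss = {}
    for v in variables:
        na = records[v].isna().to_numpy()
        miss[v] = int(na.sum())
        mask &= ~na
    out = records[mask].copy()
    return out, {"n_in": len(records), "n_kept": len(out), "missing_per_variable": miss}


def write_registry(records: pd.DataFrame, path, administrations: pd.DataFrame | None = None,
                   administrations_path=None) -> None:
    """Write records (and optionally administrations) back to CSV with NA cells empty."""
    records.to_csv(path, index=False, na_rep="")
    if administrations is not None and administrations_path is not None:
        administrations.to_csv(administrations_path, index=False, na_rep="")
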