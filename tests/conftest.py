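import numpy as np
import pandas as pd
import pytest

from painpro import morphine, registry, scores, simulate


@pytest.fixture(scope="session")
def paperlike():
    """One mid-sized paper-like synthetic registry, generated once per session."""
    cfg = simulate.default_paperlike_config(n=2500, seed=7)
    records, admin, truth = simulate.generate(cfg)
    return records, admin, truth


@pytest.fixture(scope="session")
def scored(paperlike):
    """Filtered + subgroup-allocated + scored registry ready for modelling."""
    records, admin, _ = paperlike
    records, admin, _ = registry.plausibility_filter(records, admin)
    records = records.copy()
    records["subgroup"] = registry.allocate_subgroup(records)
    records = records[~records["subgroup"].isin(registry.EXCLUSION_TOKENS)]
    out = scores.score_registry(records)
    out["opioid_use"] = morphine.opioid_use_flag(out, admin).to_numpy()
    out["me_24h"] = morphine.me_24h(admin, out["patient_id"]).to_numpy()
    return out


@pytest.fixture()
def tiny_registry_csv(tmp_path):
    """A three-patient registry CSV plus companion administrations file."""
    rows = pd.DataFrame({
        "patient_id": ["A1", "A2", "A3"],
        "sex": ["female", "male", "female"],
        "age": ["71", "64", "58"],
        "weight": ["80", "92.5", "66"],
        "anesthesia_primary": ["GA", "SA", "SA"],
        "pnb_mode": ["none", "continuous", "single"],
        "pnb_site": ["", "femoral", "adductor_canal"],
        "country_income": ["high", "high", "middle_low"],
        "enrolment_period": ["P2013_2017", "P2013_2017", "P2017_2020"],
        "oands_flag": ["false", "true", "false"],
        "worst_pain": ["6", "8", "4"],
        "least_pain": ["2", "3", "0"],
        "time_severe_pct": ["30", "50", "10"],
        "opioid_pacu": ["true", "true", "false"],
        "opioid_ward": ["false", "true", "false"],
    })
    path = tmp_path / "registry.csv"
    rows.to_csv(path, index=False)
    admin = pd.DataFrame({
        "patient_id": ["A1", "A2", "A2"],
        "drug": ["morphine", "morphine", "oxycodone"],
        "route": ["oral", "iv", "oral"],
        "dose_mg": ["10", "5", "20"],
    })
    admin_path = tmp_path / "administrations.csv"
    admin.to_csv(admin_path, index=False)
    return path, admin_path
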