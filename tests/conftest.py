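import pandas as pd
import pytest

from smicvd.risk import default_equation
from smicvd.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def equation():
    return default_equation()


@pytest.fixture(scope="session")
def small_cohort():
    """20k-person default-condition cohort shared across read-only tests."""
    cfg = SimulationConfig(n_total=20_000, seed=42)
    persons, contacts = generate_cohort(cfg)
    return cfg, persons, contacts


def make_person(**overrides) -> dict:
    """A fully specified eligible person record; overrides patch fields."""
    base = {
        "person_id": "P0000001",
        "sex": "F",
        "age_at_index": 55.0,
        "ethnicity_records": "european_other",
        "deprivation_quintile": 3,
        "smoker_status": "never",
        "diabetes": False,
        "atrial_fibrillation": False,
        "family_history": False,
        "sbp": 128.0,
        "dbp": 78.0,
        "tchdl": 3.8,
        "bmi": 27.0,
        "bp_lowering": False,
        "lipid_lowering": False,
        "antithrombotic": False,
        "prior_cvd": False,
        "prior_renal_failure": False,
        "index_date": "2010-06-15",
        "ethnicity": "european_other",
    }
    base.update(overrides)
    return base


def person_frame(records) -> pd.DataFrame:
    return pd.DataFrame(records)
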