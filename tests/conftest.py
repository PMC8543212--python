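import numpy as np
import pandas as pd
import pytest

from coolmatch import SimulationConfig, generate_cohort
from coolmatch.phenotype import derive_outcomes, impute_cooling_day2, \
    select_cohort


def derive_analysis(infants, daily, years=(2010, 2017)):
    daily = impute_cooling_day2(daily)
    eligible, _ = select_cohort(infants, daily, years)
    return derive_outcomes(infants, daily, eligible)


@pytest.fixture(scope="session")
def cohort_small():
    """2000-infant cohort under default (study-condition) settings."""
    cfg = SimulationConfig(n_infants=2000, seed=5)
    infants, daily, gt = generate_cohort(cfg)
    return cfg, infants, daily, gt


@pytest.fixture(scope="session")
def cohort_large():
    """20000-infant cohort for recovery / fidelity checks."""
    cfg = SimulationConfig(n_infants=20000, seed=11)
    infants, daily, gt = generate_cohort(cfg)
    return cfg, infants, daily, gt


@pytest.fixture(scope="session")
def analysis_large(cohort_large):
    cfg, infants, daily, gt = cohort_large
    return derive_analysis(infants, daily)


@pytest.fixture(scope="session")
def analysis_small(cohort_small):
    cfg, infants, daily, gt = cohort_small
    return derive_analysis(infants, daily)


def make_daily(rows):
    """Daily table from dicts; unspecified flags default to 0 / 'none'."""
    defaults = {"cooled": 0.0, "pn": 0.0, "antibiotics": 0,
                "nil_by_mouth": 0, "central_line": 0, "enteral_feed": 0,
                "maternal_milk": 0, "suckled_at_breast": 0,
                "blood_culture": "none", "nec_diagnosis_recorded": 0,
                "hypoglycaemia_recorded": 0, "died_today": 0}
    full = [{**defaults, **r} for r in rows]
    return pd.DataFrame(full)


def make_infant(infant_id="A", birth_year=2012, ga_weeks=39, ga_days=0,
                **kwargs):
    base = {
        "infant_id": infant_id, "birth_year": birth_year, "region": "england",
        "network": "N01", "male": 1, "gestational_weeks": ga_weeks,
        "gestational_days": ga_days, "birth_weight_g": 3400, "caesarean": 0,
        "maternal_age": 30.0, "ethnicity": "white", "deprivation_decile": 5.0,
        "smoking": "no", "maternal_diabetes": 0, "maternal_hypothyroidism": 0,
        "maternal_fever": 0, "chorioamnionitis": 0, "primiparous": 1,
        "multiple_birth": 0, "rom_hours": 6.0, "apgar1_band": "2-4",
        "apgar5_band": "5-7", "cord_ph_band": ">7.0", "chest_compressions": 0,
        "resus_drugs": 0, "intubated": 1, "time_to_first_breath_min": 3.0,
        "admission_temp_c": 34.8, "admission_hr": 120.0,
        "admission_glucose": 3.5, "admission_bp": 45.0,
        "admission_spo2": 95.0, "inotropes_day1": 0, "ventilated_day1": 1,
        "nitric_oxide_day1": 0, "early_onset_infection": 0,
        "postnatal_transfer_24h": 0, "severe_nec": 0, "alive_at_discharge": 1,
        "discharge_day": 10, "discharge_weight_g": 3500.0,
        "breastfeeding_at_discharge": 0,
    }
    base.update(kwargs)
    return base


def simple_stay(infant_id, n_days, cooled_days=3, death_day=None, **flags):
    """n_days of daily rows with a standard cooling course."""
    rows = []
    for day in range(1, n_days + 1):
        row = {"infant_id": infant_id, "day": day,
               "cooled": 1.0 if day <= cooled_days else 0.0}
        if death_day is not None and day == death_day:
            row["died_today"] = 1
        for key, days in flags.items():
            if day in days:
                row[key] = 1
        rows.append(row)
    return rows
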