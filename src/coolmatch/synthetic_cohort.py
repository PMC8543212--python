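"""Synthetic cohort generator with known ground truth.

Emulates the structure of a national neonatal EHR extract for infants
receiving 3-day therapeutic hypothermia: one infant-level table of
background covariates and discharge fields, and one daily table (one row
per infant-day, day 1 = day of birth) of treatment and event flags.

The generator is built so that every downstream stage is exactly testable:

* exposure (parenteral nutrition on a cooled day) is assigned by a Bernoulli
  draw on a configured logistic propensity over a fixed covariate encoding
  (:func:`true_design`), so propensity-model recovery can be asserted;
* clinical-condition covariates load on one latent severity factor (a
  one-factor Gaussian copula), which also drives outcome probabilities —
  this creates confounding by indication while keeping exposure independent
  of severity *given* the observed covariates, so matching on them is
  sufficient for unbiasedness;
* daily records are constructed to realise the drawn outcome flags exactly
  (e.g. a qualifying >=5-day antibiotic run is planted if and only if the
  pragmatic late-onset infection flag is true), so derived phenotypes can be
  compared to ground truth with equality.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from coolmatch.config import ConfigurationError, SimulationConfig
from coolmatch import growth

logger = logging.getLogger(__name__)

INFANT_COLUMNS = [
    "infant_id", "birth_year", "region", "network", "male",
    "gestational_weeks", "gestational_days", "birth_weight_g", "caesarean",
    "maternal_age", "ethnicity", "deprivation_decile", "smoking",
    "maternal_diabetes", "maternal_hypothyroidism", "maternal_fever",
    "chorioamnionitis", "primiparous", "multiple_birth", "rom_hours",
    "apgar1_band", "apgar5_band", "cord_ph_band", "chest_compressions",
    "resus_drugs", "intubated", "time_to_first_breath_min",
    "admission_temp_c", "admission_hr", "admission_glucose", "admission_bp",
    "admission_spo2", "inotropes_day1", "ventilated_day1",
    "nitric_oxide_day1", "early_onset_infection", "postnatal_transfer_24h",
    "severe_nec", "alive_at_discharge", "discharge_day",
    "discharge_weight_g", "breastfeeding_at_discharge",
]

DAILY_COLUMNS = [
    "infant_id", "day", "cooled", "pn", "antibiotics", "nil_by_mouth",
    "central_line", "enteral_feed", "maternal_milk", "suckled_at_breast",
    "blood_culture", "nec_diagnosis_recorded", "hypoglycaemia_recorded",
    "died_today",
]

GROUND_TRUTH_COLUMNS = [
    "infant_id", "true_propensity", "exposed", "eligible", "survived",
    "culture_positive_loi", "pragmatic_loi", "pragmatic_nec", "severe_nec",
    "hypoglycaemia", "breastfeeding_at_discharge", "length_of_stay",
    "central_line_days", "pn_duration_days", "first_maternal_milk_day",
    "first_suckle_day", "discharge_weight_sds",
]


@dataclass
class GroundTruth:
    """Per-infant truth used by the generator, for exact downstream checks."""

    table: pd.DataFrame
    effects: dict[str, float]
    propensity_coefficients: dict[str, float]


# ---------------------------------------------------------------------------
# copula helpers
# ---------------------------------------------------------------------------

def _corr_bernoulli(rng: np.random.Generator, s: np.ndarray, loading: float,
                    p: float) -> np.ndarray:
    """Bernoulli(p) marginally, correlated with latent severity ``s``."""
    loading = float(np.clip(loading, -0.999, 0.999))
    z = loading * s + np.sqrt(1.0 - loading ** 2) * rng.standard_normal(s.shape)
    return (z > norm.isf(p)).astype(np.int8)


def _corr_ordinal(rng: np.random.Generator, s: np.ndarray, loading: float,
                  probs: list[float]) -> np.ndarray:
    """Ordered-category index 0..k-1 with given marginals, copula-linked."""
    loading = float(np.clip(loading, -0.999, 0.999))
    z = loading * s + np.sqrt(1.0 - loading ** 2) * rng.standard_normal(s.shape)
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()
    cuts = norm.ppf(np.cumsum(p)[:-1])
    return np.searchsorted(cuts, z, side="right").astype(np.int8)


def _banded(rng, s, loading, prob_map: dict[str, float], labels: list[str],
            missing_rate: float) -> np.ndarray:
    """Banded categorical with an independent missing mechanism."""
    conditional = [prob_map[lab] for lab in labels]
    idx = _corr_ordinal(rng, s, loading, conditional)
    out = np.asarray(labels, dtype=object)[idx]
    if missing_rate > 0:
        out = out.copy()
        out[rng.random(s.shape[0]) < missing_rate] = "missing"
    return out


# ---------------------------------------------------------------------------
# true propensity encoding
# ---------------------------------------------------------------------------

def true_design(infants: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Fixed covariate encoding on which the true exposure model is stated.

    Columns are selected by the keys of ``config.true_propensity`` (always
    including the intercept), so the configured coefficient vector and the
    returned matrix line up one-to-one.
    """
    m = config.covariate_marginals
    year_mid = (config.year_range[0] + config.year_range[1]) / 2.0
    candidates = {
        "intercept": np.ones(len(infants)),
        "birth_weight_z": (infants["birth_weight_g"].to_numpy(float)
                           - m["birth_weight_mean"]) / m["birth_weight_sd"],
        "apgar5_low": (infants["apgar5_band"] == "0-1").to_numpy(float),
        "ph_low": (infants["cord_ph_band"] == "<6.9").to_numpy(float),
        "ph_missing": (infants["cord_ph_band"] == "missing").to_numpy(float),
        "inotropes_day1": infants["inotropes_day1"].to_numpy(float),
        "ventilated_day1": infants["ventilated_day1"].to_numpy(float),
        "chest_compressions": infants["chest_compressions"].to_numpy(float),
        "intubated": infants["intubated"].to_numpy(float),
        "smoking_yes": (infants["smoking"] == "yes").to_numpy(float),
        "male": infants["male"].to_numpy(float),
        "year_centered": infants["birth_year"].to_numpy(float) - year_mid,
    }
    cols = {}
    for name in config.true_propensity:
        if name not in candidates:
            raise ConfigurationError(
                f"unknown true-propensity term {name!r}; known terms: "
                f"{sorted(candidates)}")
        cols[name] = candidates[name]
    return pd.DataFrame(cols, index=infants.index)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _empty_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    infants = pd.DataFrame(columns=INFANT_COLUMNS)
    daily = pd.DataFrame(columns=DAILY_COLUMNS)
    gt = pd.DataFrame(columns=GROUND_TRUTH_COLUMNS)
    return infants, daily, gt


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (infant table, daily table, ground truth) from ``config``.

    Identical ``config`` (including seed) yields byte-identical tables.
    """
    config.validate()
    n = int(config.n_infants)
    if n == 0:
        infants, daily, gt = _empty_tables()
        return infants, daily, GroundTruth(gt, dict(config.true_effects),
                                           dict(config.true_propensity))

    rng = np.random.default_rng(config.seed)
    m = config.covariate_marginals
    lo = config.severity_loadings
    eff = config.true_effects
    base = config.outcome_base_rates
    sev = config.outcome_severity_slopes
    y0, y1 = config.year_range

    ids = np.array([f"I{i:06d}" for i in range(1, n + 1)], dtype=object)
    s = rng.standard_normal(n)  # latent severity, higher = sicker

    # ---- background covariates -------------------------------------------
    birth_year = rng.integers(y0, y1 + 1, n)
    region = rng.choice(list(m["region"]), n, p=list(m["region"].values()))
    network = np.array([f"N{k:02d}" for k in
                        rng.integers(1, m["n_networks"] + 1, n)], dtype=object)
    male = (rng.random(n) < m["male"]).astype(np.int8)
    ga = rng.normal(m["gestational_age_mean"], m["gestational_age_sd"], n)
    ga = np.clip(ga, 33.0, 43.9)
    ga_weeks = np.floor(ga).astype(int)
    ga_days = np.clip(np.round((ga - ga_weeks) * 7), 0, 6).astype(int)
    bw_z = lo["birth_weight"] * s + np.sqrt(1 - lo["birth_weight"] ** 2) \
        * rng.standard_normal(n)
    birth_weight = np.round(m["birth_weight_mean"]
                            + m["birth_weight_sd"] * bw_z).astype(int)
    birth_weight = np.clip(birth_weight, 1200, 6500)
    caesarean = (rng.random(n) < m["caesarean"]).astype(np.int8)
    maternal_age = np.clip(np.round(
        rng.normal(m["maternal_age_mean"], m["maternal_age_sd"], n)), 14, 55)
    ethnicity = rng.choice(list(m["ethnicity"]), n,
                           p=list(m["ethnicity"].values()))
    deprivation = rng.integers(1, 11, n).astype(float)
    smoking = rng.choice(list(m["smoking"]), n, p=list(m["smoking"].values()))
    diabetes = (rng.random(n) < m["maternal_diabetes"]).astype(np.int8)
    hypothyroid = (rng.random(n) < m["maternal_hypothyroidism"]).astype(np.int8)
    fever = (rng.random(n) < m["maternal_fever"]).astype(np.int8)
    chorio = (rng.random(n) < m["chorioamnionitis"]).astype(np.int8)
    primip = (rng.random(n) < m["primiparous"]).astype(np.int8)
    multiple = (rng.random(n) < m["multiple_birth"]).astype(np.int8)
    rom_hours = np.round(rng.exponential(
        m["rom_hours_median"] / np.log(2), n), 1)

    apgar_labels = ["0-1", "2-4", "5-7", "8-10"]
    a5 = dict(m["apgar5_band"])
    a1 = dict(m["apgar1_band"])
    apgar5 = _banded(rng, s, lo["apgar5_band"], a5, apgar_labels, a5["missing"])
    apgar1 = _banded(rng, s, lo["apgar1_band"], a1, apgar_labels, a1["missing"])
    ph = dict(m["cord_ph_band"])
    cord_ph = _banded(rng, s, lo["cord_ph_band"], ph,
                      [">7.0", "6.9-7.0", "<6.9"], ph["missing_rate"])

    chest = _corr_bernoulli(rng, s, lo["chest_compressions"],
                            m["chest_compressions"])
    drugs = _corr_bernoulli(rng, s, lo["resus_drugs"], m["resus_drugs"])
    intubated = _corr_bernoulli(rng, s, lo["intubated"], m["intubated"])
    ttfb = np.round(np.clip(
        np.exp(rng.normal(1.2 + 0.4 * lo["time_to_first_breath"] * s, 0.6, n)),
        0, 60), 1)
    ventilated = _corr_bernoulli(rng, s, lo["ventilated_day1"],
                                 m["ventilated_day1"])
    inotropes = _corr_bernoulli(rng, s, lo["inotropes_day1"],
                                m["inotropes_day1"])
    nitric = _corr_bernoulli(rng, s, lo["nitric_oxide_day1"],
                             m["nitric_oxide_day1"])
    eoi = _corr_bernoulli(rng, s, lo["early_onset_infection"],
                          m["early_onset_infection"])
    transfer = (rng.random(n) < m["postnatal_transfer_24h"]).astype(np.int8)
    severe_nec = (rng.random(n) < m["severe_nec"]).astype(np.int8)

    # admission condition prior to cooling (passively cooled on admission)
    adm_temp = np.round(rng.normal(34.8, 0.9, n) - 0.25 * s, 1)
    adm_hr = np.round(rng.normal(118, 16, n) + 4.0 * s)
    adm_glucose = np.round(np.clip(rng.normal(3.6, 1.2, n) - 0.25 * s, 0.3,
                                   12.0), 1)
    adm_bp = np.round(rng.normal(46, 8, n) - 2.5 * s)
    adm_spo2 = np.round(np.clip(rng.normal(95, 3, n) - 1.2 * s, 55, 100))

    infants = pd.DataFrame({
        "infant_id": ids, "birth_year": birth_year, "region": region,
        "network": network, "male": male, "gestational_weeks": ga_weeks,
        "gestational_days": ga_days, "birth_weight_g": birth_weight,
        "caesarean": caesarean, "maternal_age": maternal_age,
        "ethnicity": ethnicity, "deprivation_decile": deprivation,
        "smoking": smoking, "maternal_diabetes": diabetes,
        "maternal_hypothyroidism": hypothyroid, "maternal_fever": fever,
        "chorioamnionitis": chorio, "primiparous": primip,
        "multiple_birth": multiple, "rom_hours": rom_hours,
        "apgar1_band": apgar1, "apgar5_band": apgar5,
        "cord_ph_band": cord_ph, "chest_compressions": chest,
        "resus_drugs": drugs, "intubated": intubated,
        "time_to_first_breath_min": ttfb, "admission_temp_c": adm_temp,
        "admission_hr": adm_hr, "admission_glucose": adm_glucose,
        "admission_bp": adm_bp, "admission_spo2": adm_spo2,
        "inotropes_day1": inotropes, "ventilated_day1": ventilated,
        "nitric_oxide_day1": nitric, "early_onset_infection": eoi,
        "postnatal_transfer_24h": transfer, "severe_nec": severe_nec,
    })

    # ---- exposure ---------------------------------------------------------
    design = true_design(infants, config)
    beta = np.array([config.true_propensity[c] for c in design.columns])
    lp = design.to_numpy(float) @ beta
    true_p = 1.0 / (1.0 + np.exp(-lp))
    exposed = (rng.random(n) < true_p).astype(np.int8)
    x = exposed.astype(float)

    def outcome_prob(name: str) -> np.ndarray:
        return np.clip(base[name] + sev[name] * s + eff.get(name, 0.0) * x,
                       0.0, 1.0)

    # ---- survival, cooling completion and length of stay ------------------
    survived = (rng.random(n) < outcome_prob("survived")).astype(np.int8)
    died = survived == 0
    death_during_cooling = died & (
        rng.random(n) < config.edge_case_rates["death_during_cooling"])
    death_day = np.zeros(n, dtype=int)
    death_day[death_during_cooling] = rng.integers(
        1, 4, int(death_during_cooling.sum()))
    late_death = died & ~death_during_cooling
    death_day[late_death] = np.clip(4 + rng.poisson(7, int(late_death.sum())),
                                    4, 60)

    los = np.clip(np.round(
        np.exp(rng.normal(np.log(10.5), 0.5, n)) + 0.9 * np.clip(s, -2, 4)
        + eff.get("length_of_stay", 0.0) * x), 4, 120).astype(int)
    los[died] = death_day[died]

    cooled_days = np.full(n, 3, dtype=int)
    cooled_days[death_during_cooling] = death_day[death_during_cooling]
    incomplete = (survived == 1) & (
        rng.random(n) < config.edge_case_rates["incomplete_cooling"])
    cooled_days[incomplete] = rng.integers(1, 3, int(incomplete.sum()))

    ga_total = ga_weeks + ga_days / 7.0
    eligible = (ga_total >= 36.0) & ((cooled_days == 3) | death_during_cooling)

    # ---- binary outcomes realised in the daily table ----------------------
    can_host_run = ~(died & (death_day <= 3))
    ploi = ((rng.random(n) < outcome_prob("pragmatic_loi"))
            & can_host_run).astype(np.int8)

    has_early_abx = rng.random(n) < 0.8
    early_len = np.where(has_early_abx, rng.integers(2, 5, n), 0)
    early_len = np.minimum(early_len, los)

    run_start = np.maximum(4, early_len + 2) + rng.integers(0, 4, n)
    run_len = rng.integers(5, 9, n)
    run_end = run_start + run_len - 1
    is_ploi = ploi == 1
    los = np.where(is_ploi, np.maximum(los, run_end), los)
    death_day = np.where(is_ploi & died, los, death_day)

    p_nec = outcome_prob("pragmatic_nec")
    p_ploi = np.clip(outcome_prob("pragmatic_loi"), 1e-9, 1.0)
    nec = (is_ploi & (rng.random(n) < np.clip(p_nec / p_ploi, 0, 1))
           ).astype(np.int8)
    fp_diag = (nec == 0) & (rng.random(n) < 0.01)
    nec_diag_day = np.where(nec == 1, run_start,
                            1 + (rng.random(n) * los).astype(int))
    has_nec_diag = (nec == 1) | fp_diag

    # non-qualifying short late antibiotic course for some unflagged infants
    short_late = (~is_ploi) & (rng.random(n) < 0.15) & (los >= 5)
    sl_start = np.maximum(4, early_len + 2) + rng.integers(0, 3, n)
    sl_len = rng.integers(1, 5, n)

    culture = ((rng.random(n) < outcome_prob("culture_positive_loi"))
               & (los >= 4)).astype(np.int8)
    culture_day = 4 + (rng.random(n) * (los - 3)).astype(int)
    commensal = (rng.random(n) < 0.05) & (los >= 1)
    commensal_day = 1 + (rng.random(n) * los).astype(int)

    hypo = (rng.random(n) < outcome_prob("hypoglycaemia")).astype(np.int8)
    hypo_day = 1 + (rng.random(n) * los).astype(int)

    bf = ((rng.random(n) < outcome_prob("breastfeeding_at_discharge"))
          & (survived == 1)).astype(np.int8)

    # ---- lines, feeds, parenteral nutrition -------------------------------
    has_cl = rng.random(n) < np.clip(0.923 + 0.056 * x, 0, 1)
    cl_days = np.where(has_cl, np.clip(np.round(
        rng.normal(5.1 + eff.get("central_line_days", 0.0) * x + 0.5 * s,
                   2.2)), 1, los), 0).astype(int)

    pn_start = np.zeros(n, dtype=int)
    pn_end = np.full(n, -1, dtype=int)
    exp_mask = exposed == 1
    pn_start[exp_mask] = rng.integers(1, 4, int(exp_mask.sum()))
    pn_start = np.minimum(pn_start, cooled_days)  # guarantee a cooled PN day
    pn_dur = 1 + rng.poisson(4, n)
    pn_end[exp_mask] = np.minimum(los[exp_mask],
                                  pn_start[exp_mask] + pn_dur[exp_mask] - 1)
    # a few unexposed infants start PN only after cooling has finished
    late_pn = (~exp_mask) & (rng.random(n) < 0.05) & (los >= 5)
    pn_start[late_pn] = 4
    pn_end[late_pn] = np.minimum(los[late_pn], 4 + rng.poisson(3, int(late_pn.sum())))
    pn_duration = np.maximum(pn_end - pn_start + 1, 0)

    has_ent = rng.random(n) < 0.9
    ent_start = np.clip(np.round(rng.normal(3.5, 1.5, n)), 1, los).astype(int)
    has_fmm = (rng.random(n) < 0.92) & (los >= 2)
    fmm_day = np.clip(np.round(rng.normal(
        4.9 + eff.get("first_maternal_milk_day", 0.0) * x, 1.5)), 1, los
    ).astype(int)
    has_suckle = (rng.random(n) < 0.55) & (survived == 1) & (los >= 5)
    suckle_day = np.clip(np.round(rng.normal(
        8.4 + eff.get("first_suckle_day", 0.0) * x, 2.0)), 3, los).astype(int)

    nbm_early = rng.random(n) < 0.7  # nil by mouth during early cooling days

    # ---- discharge weight -------------------------------------------------
    pma_week = ga_weeks + (los - 1) // 7
    dw_sds = rng.normal(-0.66 + eff.get("discharge_weight_sds", 0.0) * x,
                        0.9, n)
    dw = np.round(growth.sds_to_weight(dw_sds, male, pma_week)).astype(float)
    dw[died] = np.nan
    # SDS recomputed from the rounded stored weight so the ground truth
    # matches the downstream derivation to machine precision
    dw_sds_out = np.where(died, np.nan,
                          growth.weight_to_sds(dw, male, pma_week))

    infants["alive_at_discharge"] = survived
    infants["discharge_day"] = los
    infants["discharge_weight_g"] = dw
    infants["breastfeeding_at_discharge"] = bf

    # covariate missingness (missing = empty field in CSV)
    miss = config.missingness_rates
    for col in ("admission_temp_c", "admission_hr", "admission_glucose",
                "admission_bp", "admission_spo2", "rom_hours",
                "time_to_first_breath_min", "maternal_age",
                "deprivation_decile"):
        rate = miss.get(col, 0.0)
        if rate > 0:
            mask = rng.random(n) < rate
            infants.loc[mask, col] = np.nan

    # ---- daily table ------------------------------------------------------
    total = int(los.sum())
    idx = np.repeat(np.arange(n), los)
    day = np.arange(total) - np.repeat(np.cumsum(los) - los, los) + 1

    cooled = (day <= cooled_days[idx]).astype(float)
    pn = ((day >= pn_start[idx]) & (day <= pn_end[idx])).astype(float)
    ab = (day <= early_len[idx]) \
        | (is_ploi[idx] & (day >= run_start[idx]) & (day <= run_end[idx])) \
        | (short_late[idx] & (day >= sl_start[idx])
           & (day <= (sl_start + sl_len - 1)[idx]) & (day <= los[idx]))
    in_nec_run = (nec[idx] == 1) & (day >= run_start[idx]) & (day <= run_end[idx])
    nbm = (nbm_early[idx] & (day <= 2)) | in_nec_run
    central = day <= cl_days[idx]
    enteral = has_ent[idx] & (day >= ent_start[idx])
    milk = has_fmm[idx] & (day >= fmm_day[idx])
    suckled = has_suckle[idx] & (day >= suckle_day[idx])
    bc = np.full(total, "none", dtype=object)
    bc[commensal[idx] & (day == commensal_day[idx])] = "commensal"
    bc[(culture[idx] == 1) & (day == culture_day[idx])] = "pathogen"
    nec_rec = has_nec_diag[idx] & (day == nec_diag_day[idx])
    hypo_rec = (hypo[idx] == 1) & (day == hypo_day[idx])
    died_today = (died[idx]) & (day == death_day[idx])

    daily = pd.DataFrame({
        "infant_id": ids[idx], "day": day, "cooled": cooled, "pn": pn,
        "antibiotics": ab.astype(np.int8), "nil_by_mouth": nbm.astype(np.int8),
        "central_line": central.astype(np.int8),
        "enteral_feed": enteral.astype(np.int8),
        "maternal_milk": milk.astype(np.int8),
        "suckled_at_breast": suckled.astype(np.int8),
        "blood_culture": bc,
        "nec_diagnosis_recorded": nec_rec.astype(np.int8),
        "hypoglycaemia_recorded": hypo_rec.astype(np.int8),
        "died_today": died_today.astype(np.int8),
    })

    # PN recording gaps in the first 4 days for a few unexposed infants
    pn_miss_rate = miss.get("pn_first4", 0.0)
    if pn_miss_rate > 0:
        pn_missing_inf = (~exp_mask) & (~late_pn) & (rng.random(n) < pn_miss_rate)
        daily.loc[pn_missing_inf[idx] & (day <= 4), "pn"] = np.nan

    daily = inject_edge_cases(
        daily, config.edge_case_rates["missing_day2_cooling"],
        seed=config.seed + 1)

    gt_table = pd.DataFrame({
        "infant_id": ids, "true_propensity": true_p, "exposed": exposed,
        "eligible": eligible.astype(np.int8), "survived": survived,
        "culture_positive_loi": culture, "pragmatic_loi": ploi,
        "pragmatic_nec": nec, "severe_nec": severe_nec,
        "hypoglycaemia": hypo, "breastfeeding_at_discharge": bf,
        "length_of_stay": los, "central_line_days": cl_days,
        "pn_duration_days": pn_duration,
        "first_maternal_milk_day": np.where(has_fmm, fmm_day, np.nan),
        "first_suckle_day": np.where(has_suckle, suckle_day, np.nan),
        "discharge_weight_sds": dw_sds_out,
    })

    return infants, daily, GroundTruth(gt_table, dict(config.true_effects),
                                       dict(config.true_propensity))


def inject_edge_cases(daily: pd.DataFrame, rate: float,
                      seed: int) -> pd.DataFrame:
    """Blank the day-2 cooling flag for a random fraction of cooled infants.

    Eligible for injection are infants recorded cooled on days 1, 2 and 3 who
    did not die on days 1-3 — exactly the infants the downstream imputation
    rule is allowed to repair.  Selection is reproducible from ``seed``.
    """
    if not (0.0 <= rate <= 1.0):
        raise ConfigurationError(f"rate must be in [0, 1], got {rate!r}")
    if rate == 0 or daily.empty:
        return daily
    d13 = daily[daily["day"] <= 3]
    cooled_all3 = d13.groupby("infant_id")["cooled"].agg(
        lambda v: len(v) == 3 and (v == 1).all())
    died_early = d13.groupby("infant_id")["died_today"].max() == 1
    candidates = cooled_all3.index[cooled_all3 & ~died_early.reindex(
        cooled_all3.index, fill_value=False)]
    rng = np.random.default_rng(seed)
    selected = set(np.asarray(candidates, dtype=object)[
        rng.random(len(candidates)) < rate])
    out = daily.copy()
    mask = (out["day"] == 2) & out["infant_id"].isin(selected)
    out.loc[mask, "cooled"] = np.nan
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(outdir: str, infants: pd.DataFrame, daily: pd.DataFrame,
                 gt: GroundTruth) -> None:
    """Write ``infants.csv``, ``daily.csv``, ``ground_truth.csv/.json``.

    CSV convention: header row, booleans as 0/1, missing values as empty
    fields.
    """
    os.makedirs(outdir, exist_ok=True)
    infants.to_csv(os.path.join(outdir, "infants.csv"), index=False)
    daily.to_csv(os.path.join(outdir, "daily.csv"), index=False)
    gt.table.to_csv(os.path.join(outdir, "ground_truth.csv"), index=False)
    with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
        json.dump({
            "true_effects": gt.effects,
            "true_propensity_coefficients": gt.propensity_coefficients,
            "n_infants": int(len(gt.table)),
        }, fh, indent=2)


def read_cohort(indir: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ``infants.csv`` and ``daily.csv`` written by :func:`write_cohort`."""
    infants = pd.read_csv(os.path.join(indir, "infants.csv"))
    daily = pd.read_csv(os.path.join(indir, "daily.csv"))
    return infants, daily
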