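"""EHR phenotype derivation: eligibility, cleaning, exposure and outcomes.

All rules operate on the two raw tables (infant-level and daily) and produce
one analysis row per eligible infant.  Day 1 is the day of birth; the
therapeutic-hypothermia window is the recorded cooled days (days 1-3 for a
completed course); "after day 3" means day >= 4 throughout.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from coolmatch.config import DataError
from coolmatch import growth

logger = logging.getLogger(__name__)

#: infant-table columns carried into the analysis table as propensity
#: covariates
COVARIATE_COLUMNS = [
    "birth_year", "region", "network", "male", "gestational_weeks",
    "gestational_days", "birth_weight_g", "caesarean", "maternal_age",
    "ethnicity", "deprivation_decile", "smoking", "maternal_diabetes",
    "maternal_hypothyroidism", "maternal_fever", "chorioamnionitis",
    "primiparous", "multiple_birth", "rom_hours", "apgar1_band",
    "apgar5_band", "cord_ph_band", "chest_compressions", "resus_drugs",
    "intubated", "time_to_first_breath_min", "admission_temp_c",
    "admission_hr", "admission_glucose", "admission_bp", "admission_spo2",
    "inotropes_day1", "ventilated_day1", "nitric_oxide_day1",
    "early_onset_infection", "postnatal_transfer_24h",
]


def _check_contiguous(daily: pd.DataFrame) -> None:
    """Days must form a contiguous 1..k range within each infant."""
    if daily.empty:
        return
    d = daily.sort_values(["infant_id", "day"])
    g = d.groupby("infant_id")["day"]
    first = g.first()
    if (first != 1).any():
        bad = first.index[first != 1][0]
        raise DataError(f"daily records for {bad!r} do not start at day 1")
    step = g.diff().dropna()
    if (step != 1).any():
        raise DataError("daily records contain gaps or duplicate days")


def impute_cooling_day2(daily: pd.DataFrame) -> pd.DataFrame:
    """Impute a missing day-2 cooling flag.

    The flag is set to true if and only if it is missing, the infant is
    recorded as cooled on both day 1 and day 3, and the infant did not die
    during the cooling period (days 1-3).  No other cell is altered, and no
    other imputation is performed anywhere in the pipeline.  Idempotent.
    """
    _check_contiguous(daily)
    if daily.empty:
        return daily
    d13 = daily[daily["day"] <= 3]
    wide = d13.pivot_table(index="infant_id", columns="day", values="cooled",
                           aggfunc="first", dropna=False)
    for day in (1, 2, 3):
        if day not in wide.columns:
            wide[day] = np.nan
    died_early = d13.groupby("infant_id")["died_today"].max() == 1
    died_early = died_early.reindex(wide.index, fill_value=False)
    target = wide.index[wide[2].isna() & (wide[1] == 1) & (wide[3] == 1)
                        & ~died_early]
    out = daily.copy()
    mask = (out["day"] == 2) & out["infant_id"].isin(set(target))
    out.loc[mask, "cooled"] = 1.0
    return out


def select_cohort(infants: pd.DataFrame, daily: pd.DataFrame,
                  years: tuple[int, int] = (2010, 2017),
                  ) -> tuple[list[str], pd.DataFrame]:
    """Apply the eligibility rules; return (eligible ids, exclusion table).

    Eligible infants have recorded gestational age >= 36+0 weeks+days, a
    birth year inside ``years`` (inclusive), and either a complete 3-day
    course of therapeutic hypothermia or death while being cooled before
    completing it.  The day-2 imputation must already have been applied.
    """
    infants = infants.reset_index(drop=True)
    ga = infants["gestational_weeks"] + infants["gestational_days"] / 7.0
    ga_ok = ga >= 36.0
    year_ok = infants["birth_year"].between(years[0], years[1])

    cooled_ok = pd.Series(False, index=infants["infant_id"])
    if not daily.empty:
        d13 = daily[daily["day"] <= 3].sort_values(["infant_id", "day"])
        g = d13.groupby("infant_id")
        n_days = g.size()
        full = g["cooled"].apply(lambda v: len(v) == 3 and (v == 1).all())
        # died during cooling: cooled on every recorded day, died on the last
        died_day = d13[d13["died_today"] == 1].groupby("infant_id")["day"].max()
        all_cooled = g["cooled"].apply(lambda v: (v == 1).all())
        last_day = g["day"].max()
        died_cooling = (died_day.reindex(n_days.index) == last_day) & all_cooled
        cooled_ok = (full | died_cooling.fillna(False)).reindex(
            infants["infant_id"], fill_value=False)
    no_daily = ~infants["infant_id"].isin(daily["infant_id"].unique()
                                          if not daily.empty else [])
    if no_daily.any():
        logger.warning("%d infants have no daily records; excluded",
                       int(no_daily.sum()))

    eligible_mask = (ga_ok & year_ok
                     & cooled_ok.reset_index(drop=True)).to_numpy()
    reasons = np.select(
        [no_daily.to_numpy(), ~ga_ok.to_numpy(), ~year_ok.to_numpy(),
         ~cooled_ok.reset_index(drop=True).to_numpy()],
        ["no_daily_records", "gestation_below_36", "year_out_of_range",
         "incomplete_cooling"], default="")
    exclusions = pd.DataFrame({
        "infant_id": infants.loc[~eligible_mask, "infant_id"].to_numpy(),
        "reason": reasons[~eligible_mask],
    })
    return infants.loc[eligible_mask, "infant_id"].tolist(), exclusions


def derive_exposure(daily: pd.DataFrame, eligible_ids: list[str]) -> pd.Series:
    """True iff parenteral nutrition is recorded on >= 1 cooled day.

    A missing PN flag never counts as exposure.
    """
    idx = pd.Index(eligible_ids, name="infant_id")
    if daily.empty:
        return pd.Series(False, index=idx, name="exposure_pn")
    d = daily[daily["infant_id"].isin(set(eligible_ids))]
    hit = d[(d["pn"] == 1) & (d["cooled"] == 1)].groupby("infant_id").size()
    return pd.Series(idx.isin(hit.index), index=idx, name="exposure_pn")


def consecutive_run(flags, min_len: int, start_after_day: int) -> bool:
    """True iff a maximal run of >= ``min_len`` consecutive true days starts
    on a day strictly greater than ``start_after_day``.

    ``flags[i]`` is the flag for day ``i + 1``.  An empty sequence is False.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    flags = list(flags)
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            start = i + 1
            length = 0
            while i < n and flags[i]:
                length += 1
                i += 1
            if length >= min_len and start > start_after_day:
                return True
        else:
            i += 1
    return False


def _antibiotic_runs(d: pd.DataFrame) -> pd.DataFrame:
    """Maximal consecutive antibiotic runs per infant (vectorised).

    Returns one row per run: infant_id, start day, length, all_nbm.
    Requires ``d`` sorted by (infant_id, day) with contiguous days.
    """
    ab = d["antibiotics"].to_numpy() == 1
    same_inf = d["infant_id"].to_numpy()
    prev_inf = np.roll(same_inf, 1)
    prev_ab = np.roll(ab, 1)
    prev_ab[0] = False
    new_run = ab & (~prev_ab | (same_inf != prev_inf))
    run_id = np.cumsum(new_run)
    rows = d.loc[ab, ["infant_id", "day", "nil_by_mouth"]].copy()
    rows["run_id"] = run_id[ab]
    runs = rows.groupby("run_id").agg(
        infant_id=("infant_id", "first"),
        start=("day", "min"),
        length=("day", "size"),
        all_nbm=("nil_by_mouth", lambda v: bool((v == 1).all())),
    )
    return runs.reset_index(drop=True)


def derive_outcomes(infants: pd.DataFrame, daily: pd.DataFrame,
                    eligible_ids: list[str],
                    growth_reference=growth) -> pd.DataFrame:
    """Build the analysis table (one row per eligible infant).

    Outcome definitions:

    * ``culture_positive_loi`` — pure growth of a recognised pathogen in a
      blood culture taken on day >= 4;
    * ``pragmatic_loi`` — a maximal run of >= 5 consecutive antibiotic days
      starting after day 3;
    * ``pragmatic_nec`` — a recorded NEC diagnosis plus a >= 5-day
      consecutive antibiotic run with nil-by-mouth on every day of the run;
    * ``severe_nec`` — recorded severe-NEC flag passed through;
    * ``survived`` — no recorded death before discharge; ``length_of_stay``
      is the discharge or death day (day-1 inclusive convention);
    * counts of central-line and parenteral-nutrition days, first maternal
      milk / first suckling day, any recorded hypoglycaemia, breastfeeding
      at discharge, and discharge weight SDS from the growth reference.
    """
    ids = list(eligible_ids)
    d = daily[daily["infant_id"].isin(set(ids))].sort_values(
        ["infant_id", "day"])
    g = d.groupby("infant_id")

    los = g["day"].max()
    survived = g["died_today"].max() == 0
    culture = d[(d["blood_culture"] == "pathogen") & (d["day"] >= 4)] \
        .groupby("infant_id").size() > 0
    runs = _antibiotic_runs(d)
    ploi_ids = set(runs.loc[(runs["length"] >= 5) & (runs["start"] > 3),
                            "infant_id"])
    nbm_run_ids = set(runs.loc[(runs["length"] >= 5) & runs["all_nbm"],
                               "infant_id"])
    nec_diag = g["nec_diagnosis_recorded"].max() == 1
    central_days = g["central_line"].sum()
    pn_days = d[d["pn"] == 1].groupby("infant_id").size()
    first_milk = d[d["maternal_milk"] == 1].groupby("infant_id")["day"].min()
    first_suckle = d[d["suckled_at_breast"] == 1].groupby("infant_id")["day"].min()
    hypo = g["hypoglycaemia_recorded"].max() == 1
    pn_recorded = d[d["day"] <= 4].groupby("infant_id")["pn"] \
        .apply(lambda v: not v.isna().any())
    enteral_day1 = d[(d["day"] == 1) & (d["enteral_feed"] == 1)] \
        .groupby("infant_id").size() > 0

    inf = infants.set_index("infant_id").loc[ids]
    out = pd.DataFrame(index=pd.Index(ids, name="infant_id"))
    out["eligible"] = True
    out["exposure_pn"] = derive_exposure(daily, ids)
    out["culture_positive_loi"] = culture.reindex(ids, fill_value=False)
    out["pragmatic_loi"] = out.index.isin(ploi_ids)
    out["pragmatic_nec"] = (nec_diag.reindex(ids, fill_value=False)
                            & out.index.isin(nbm_run_ids))
    out["severe_nec"] = inf["severe_nec"].astype(bool)
    out["survived"] = survived.reindex(ids, fill_value=False)
    out["length_of_stay"] = los.reindex(ids)
    out["hypoglycaemia"] = hypo.reindex(ids, fill_value=False)
    out["breastfeeding_at_discharge"] = inf["breastfeeding_at_discharge"] \
        .astype(bool)
    out["first_suckle_day"] = first_suckle.reindex(ids)
    out["first_maternal_milk_day"] = first_milk.reindex(ids)
    out["central_line_days"] = central_days.reindex(ids, fill_value=0).astype(int)
    out["pn_duration_days"] = pn_days.reindex(ids, fill_value=0).astype(int)
    out["nutrition_complete_first4"] = pn_recorded.reindex(ids,
                                                           fill_value=True)
    out["enteral_day1"] = enteral_day1.reindex(ids, fill_value=False)

    weight = inf["discharge_weight_g"]
    pma_week = inf["gestational_weeks"] + (out["length_of_stay"] - 1) // 7
    with np.errstate(invalid="ignore"):
        sds = growth_reference.weight_to_sds(weight.to_numpy(float),
                                             inf["male"].to_numpy(),
                                             pma_week.to_numpy())
    n_failed = int(np.isnan(sds).sum() - weight.isna().sum())
    if n_failed > 0:
        logger.warning("growth reference lookup failed for %d infants; "
                       "SDS left missing", n_failed)
    out["discharge_weight_sds"] = sds

    for col in COVARIATE_COLUMNS:
        out[col] = inf[col]
    return out.reset_index()


def suppress_small_counts(count: int, threshold: int = 5) -> str:
    """Disclosure control: render counts 1..threshold-1 as ``"<threshold"``."""
    count = int(count)
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    if 1 <= count < threshold:
        return f"<{threshold}"
    return str(count)
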