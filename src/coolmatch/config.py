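"""Configuration objects for the simulation and the pipeline.

The simulation defaults encode the study conditions the generator emulates:
covariate marginals of a UK national cohort of term and near-term infants
cooled for hypoxic-ischaemic encephalopathy, an exposure (parenteral
nutrition during cooling) received by roughly one infant in four with a
small upward calendar-time trend, and outcome rates of the order seen in
that population (culture-positive late-onset infection well under 1%,
survival around 90%, median stay under two weeks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value is structurally invalid."""


class DataError(ValueError):
    """Raised when an input table violates a structural precondition."""


class EstimationError(RuntimeError):
    """Raised when a model fit is impossible or fails to converge."""


# ---------------------------------------------------------------------------
# Simulation defaults
# ---------------------------------------------------------------------------

#: Marginal distributions of background covariates (proportions for binary
#: covariates, parameter dicts otherwise).  Band probabilities for cord pH
#: are conditional on the value being recorded; ``missing_rate`` is the
#: probability the value is missing.
DEFAULT_MARGINALS: dict[str, Any] = {
    "male": 0.55,
    "gestational_age_mean": 39.4,
    "gestational_age_sd": 1.6,
    "birth_weight_mean": 3385.0,
    "birth_weight_sd": 621.0,
    "caesarean": 0.47,
    "maternal_age_mean": 30.5,
    "maternal_age_sd": 6.2,
    "smoking": {"yes": 0.14, "no": 0.70, "missing": 0.16},
    "ethnicity": {"white": 0.65, "asian": 0.10, "black": 0.07, "other": 0.18},
    "maternal_diabetes": 0.042,
    "maternal_hypothyroidism": 0.02,
    "maternal_fever": 0.04,
    "chorioamnionitis": 0.13,
    "primiparous": 0.535,
    "multiple_birth": 0.02,
    "rom_hours_median": 6.0,
    "cord_ph_band": {">7.0": 0.444, "6.9-7.0": 0.233, "<6.9": 0.323,
                     "missing_rate": 0.295},
    "apgar5_band": {"0-1": 0.155, "2-4": 0.375, "5-7": 0.30, "8-10": 0.085,
                    "missing": 0.085},
    "apgar1_band": {"0-1": 0.35, "2-4": 0.35, "5-7": 0.17, "8-10": 0.05,
                    "missing": 0.08},
    "chest_compressions": 0.37,
    "resus_drugs": 0.155,
    "intubated": 0.645,
    "ventilated_day1": 0.80,
    "inotropes_day1": 0.255,
    "nitric_oxide_day1": 0.05,
    "early_onset_infection": 0.03,
    "postnatal_transfer_24h": 0.45,
    "severe_nec": 0.003,
    "n_networks": 12,
    "region": {"england": 0.85, "wales": 0.06, "scotland": 0.09},
}

#: Loadings of each clinical-condition covariate on the single latent
#: severity factor (a one-factor Gaussian copula).  Positive = more likely
#: (or, for ordered bands listed best-to-worst, worse) in sicker infants.
#: Setting all loadings to zero recovers fully independent covariates.
DEFAULT_SEVERITY_LOADINGS: dict[str, float] = {
    "apgar5_band": -0.60,   # bands listed worst-to-best
    "apgar1_band": -0.55,
    "cord_ph_band": 0.50,   # bands listed best-to-worst
    "chest_compressions": 0.50,
    "resus_drugs": 0.50,
    "intubated": 0.45,
    "ventilated_day1": 0.45,
    "inotropes_day1": 0.50,
    "nitric_oxide_day1": 0.40,
    "early_onset_infection": 0.20,
    "birth_weight": -0.10,
    "time_to_first_breath": 0.50,
}

#: True exposure model: coefficients on the fixed encoding produced by
#: :func:`coolmatch.synthetic_cohort.true_design`.  Sicker infants are less
#: likely to be started on parenteral nutrition (confounding by indication);
#: the calendar-year coefficient of 0.04 on the logit corresponds to a trend
#: of about +0.007/year on the probability scale at an exposure proportion
#: near 0.25.  The intercept is calibrated so the marginal exposure
#: proportion is close to 24.5%.
DEFAULT_TRUE_PROPENSITY: dict[str, float] = {
    "intercept": -0.815,
    "birth_weight_z": -0.15,
    "apgar5_low": -0.30,
    "ph_low": -0.25,
    "ph_missing": 0.15,
    "inotropes_day1": -0.30,
    "ventilated_day1": -0.20,
    "chest_compressions": -0.20,
    "smoking_yes": 0.20,
    "year_centered": 0.04,
}

#: True exposure effects: risk differences (probability scale) for binary
#: outcomes, additive shifts (outcome units) for continuous ones.
DEFAULT_TRUE_EFFECTS: dict[str, float] = {
    "culture_positive_loi": 0.006,
    "pragmatic_loi": 0.008,
    "pragmatic_nec": -0.003,
    "survived": 0.031,
    "hypoglycaemia": -0.021,
    "breastfeeding_at_discharge": -0.006,
    "length_of_stay": 0.8,
    "central_line_days": 0.9,
    "first_maternal_milk_day": -0.25,
    "first_suckle_day": 0.2,
    "discharge_weight_sds": 0.02,
}

#: Baseline (unexposed, average-severity) outcome rates / levels.
DEFAULT_OUTCOME_BASE: dict[str, float] = {
    "culture_positive_loi": 0.003,
    "pragmatic_loi": 0.253,
    "pragmatic_nec": 0.014,
    "survived": 0.895,
    "hypoglycaemia": 0.19,
    "breastfeeding_at_discharge": 0.47,
}

#: Increase in each binary outcome probability per SD of latent severity.
DEFAULT_OUTCOME_SEVERITY: dict[str, float] = {
    "culture_positive_loi": 0.002,
    "pragmatic_loi": 0.08,
    "pragmatic_nec": 0.006,
    "survived": -0.045,
    "hypoglycaemia": 0.02,
    "breastfeeding_at_discharge": -0.05,
}

DEFAULT_MISSINGNESS: dict[str, float] = {
    "admission_temp_c": 0.10,
    "admission_bp": 0.20,
    "admission_glucose": 0.15,
    "admission_hr": 0.10,
    "admission_spo2": 0.15,
    "rom_hours": 0.30,
    "time_to_first_breath_min": 0.20,
    "maternal_age": 0.02,
    "deprivation_decile": 0.05,
    "pn_first4": 0.03,
}

DEFAULT_EDGE_CASES: dict[str, float] = {
    # fraction of fully cooled survivors whose day-2 cooling flag is blanked
    "missing_day2_cooling": 0.05,
    # fraction of deaths that occur during the 3-day cooling period
    "death_during_cooling": 0.25,
    # fraction of infants whose cooling stops early without death (ineligible)
    "incomplete_cooling": 0.015,
}


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= float(value) <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")


@dataclass
class SimulationConfig:
    """Ground-truth specification for the synthetic cohort generator."""

    n_infants: int = 6030
    seed: int = 0
    year_range: tuple[int, int] = (2010, 2017)
    covariate_marginals: dict[str, Any] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS))
    severity_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY_LOADINGS))
    true_propensity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_PROPENSITY))
    true_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_EFFECTS))
    outcome_base_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_BASE))
    outcome_severity_slopes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_SEVERITY))
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    edge_case_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_CASES))

    def validate(self) -> None:
        if int(self.n_infants) < 0:
            raise ConfigurationError(
                f"n_infants must be >= 0, got {self.n_infants}")
        y0, y1 = self.year_range
        if y1 < y0:
            raise ConfigurationError(f"invalid year_range {self.year_range}")
        for name, rate in {**self.missingness_rates,
                           **self.edge_case_rates}.items():
            _check_prob(name, rate)
        for name, rate in self.outcome_base_rates.items():
            _check_prob(f"outcome_base_rates[{name}]", rate)
        m = self.covariate_marginals
        for name in ("male", "caesarean", "maternal_diabetes", "chorioamnionitis",
                     "primiparous", "chest_compressions", "intubated",
                     "ventilated_day1", "inotropes_day1"):
            if name in m:
                _check_prob(name, m[name])

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["year_range"] = list(self.year_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        if "year_range" in d:
            d["year_range"] = tuple(d["year_range"])
        base = cls()
        # dict-valued fields are merged over the defaults so a YAML file may
        # override a single entry without restating the whole mapping
        for key in ("covariate_marginals", "severity_loadings", "true_propensity",
                    "true_effects", "outcome_base_rates",
                    "outcome_severity_slopes", "missingness_rates",
                    "edge_case_rates"):
            if key in d:
                merged = dict(getattr(base, key))
                merged.update(d[key])
                d[key] = merged
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (simulate → derive → … → report)."""

    outdir: str = "coolmatch_run"
    n_infants: int = 6030
    seed: int = 0
    m_replications: int = 25
    years: tuple[int, int] = (2010, 2017)
    restrict_years_region: bool = False       # sensitivity: 2012-2017, England/Wales
    require_complete_nutrition: bool = False  # sensitivity: nutrition recorded days 1-4
    include_day1_enteral: bool = False        # sensitivity: extra propensity covariate
    strict_12_groups: bool = False            # drop missing-pH infants from matching
    ridge: float = 1e-6
    suppression_threshold: int = 5
    simulation_overrides: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.m_replications < 1:
            raise ConfigurationError("m_replications must be >= 1")
        if self.suppression_threshold < 1:
            raise ConfigurationError("suppression_threshold must be >= 1")
        if self.ridge < 0:
            raise ConfigurationError("ridge must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(d["years"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
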