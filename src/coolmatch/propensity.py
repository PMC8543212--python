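"""Propensity-score estimation for parenteral nutrition during cooling.

Logistic regression of the exposure on all background covariates, with an
explicit ``missing`` level for categorical covariates (no infant is dropped
for covariate missingness) and a missing-indicator + zero-fill convention
for continuous ones.  A small ridge penalty (excluding the intercept) keeps
the fit finite under separation or collinearity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from coolmatch.config import ConfigurationError, EstimationError

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: the full background-covariate list of the primary analysis
DEFAULT_COVARIATES: dict[str, str] = {
    "male": CONTINUOUS,
    "maternal_age": CONTINUOUS,
    "ethnicity": CATEGORICAL,
    "deprivation_decile": CONTINUOUS,
    "smoking": CATEGORICAL,
    "maternal_diabetes": CONTINUOUS,
    "maternal_hypothyroidism": CONTINUOUS,
    "maternal_fever": CONTINUOUS,
    "chorioamnionitis": CONTINUOUS,
    "primiparous": CONTINUOUS,
    "multiple_birth": CONTINUOUS,
    "rom_hours": CONTINUOUS,
    "gestational_weeks": CONTINUOUS,
    "birth_weight_g": CONTINUOUS,
    "caesarean": CONTINUOUS,
    "apgar1_band": CATEGORICAL,
    "apgar5_band": CATEGORICAL,
    "cord_ph_band": CATEGORICAL,
    "chest_compressions": CONTINUOUS,
    "resus_drugs": CONTINUOUS,
    "intubated": CONTINUOUS,
    "time_to_first_breath_min": CONTINUOUS,
    "admission_temp_c": CONTINUOUS,
    "admission_hr": CONTINUOUS,
    "admission_glucose": CONTINUOUS,
    "admission_bp": CONTINUOUS,
    "admission_spo2": CONTINUOUS,
    "inotropes_day1": CONTINUOUS,
    "ventilated_day1": CONTINUOUS,
    "nitric_oxide_day1": CONTINUOUS,
    "early_onset_infection": CONTINUOUS,
    "postnatal_transfer_24h": CONTINUOUS,
    "network": CATEGORICAL,
    "birth_year": CONTINUOUS,
}


@dataclass
class PropensitySpec:
    """Covariate list, interactions and penalty for the propensity model."""

    covariates: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES))
    interactions: list[tuple[str, str]] = field(default_factory=list)
    ridge: float = 1e-6
    include_day1_enteral: bool = False

    def validate(self) -> None:
        if self.ridge < 0:
            raise ConfigurationError("ridge penalty must be >= 0")
        for kind in self.covariates.values():
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise ConfigurationError(f"unknown covariate kind {kind!r}")
        for a, b in self.interactions:
            for name in (a, b):
                if name not in self.covariates:
                    raise ConfigurationError(
                        f"interaction references undeclared covariate {name!r}")


def default_spec(include_day1_enteral: bool = False,
                 ridge: float = 1e-6) -> PropensitySpec:
    cov = dict(DEFAULT_COVARIATES)
    if include_day1_enteral:
        cov["enteral_day1"] = CONTINUOUS
    return PropensitySpec(covariates=cov, ridge=ridge,
                          include_day1_enteral=include_day1_enteral)


@dataclass
class PropensityFit:
    coefficients: pd.Series     # named, includes "intercept"
    standard_errors: pd.Series
    scores: pd.Series           # per-infant, in (0, 1), indexed like input
    converged: bool
    c_statistic: float
    n_used: int
    ridge: float


def _encode_block(df: pd.DataFrame, name: str, kind: str) -> pd.DataFrame:
    col = df[name]
    if kind == CONTINUOUS:
        vals = pd.to_numeric(col, errors="coerce")
        block = pd.DataFrame({name: vals.fillna(0.0)})
        if vals.isna().any():
            block[f"{name}__missing"] = vals.isna().astype(float)
        return block
    # categorical: explicit missing level, first (sorted) level as reference
    as_str = col.astype(object).where(col.notna(), "missing").astype(str)
    levels = sorted(as_str.unique())
    ref = levels[0]
    return pd.DataFrame({
        f"{name}={lev}": (as_str == lev).astype(float)
        for lev in levels if lev != ref
    })


def build_design_matrix(analysis: pd.DataFrame, spec: PropensitySpec,
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Encode the analysis table into a numeric design matrix (no intercept).

    No row is dropped for covariate missingness; constant columns are
    dropped with a warning.  Interaction terms are products of the encoded
    column blocks of the two covariates.
    """
    spec.validate()
    blocks: dict[str, pd.DataFrame] = {}
    for name, kind in spec.covariates.items():
        if name not in analysis.columns:
            raise ConfigurationError(f"covariate {name!r} not in table")
        blocks[name] = _encode_block(analysis, name, kind)
    parts = list(blocks.values())
    for a, b in spec.interactions:
        prod = {}
        for ca in blocks[a].columns:
            for cb in blocks[b].columns:
                prod[f"{ca}*{cb}"] = blocks[a][ca] * blocks[b][cb]
        parts.append(pd.DataFrame(prod))
    if parts:
        X = pd.concat(parts, axis=1)
    else:
        X = pd.DataFrame(index=analysis.index)
    constant = [c for c in X.columns if X[c].nunique(dropna=False) <= 1]
    if constant:
        logger.warning("dropping constant design columns: %s", constant)
        X = X.drop(columns=constant)
    X.index = analysis.index
    return X, list(X.columns)


def fit_propensity(X: pd.DataFrame, exposure, ridge: float = 1e-6,
                   ) -> PropensityFit:
    """Ridge-penalised logistic fit of exposure on the design matrix.

    Maximises ``loglik(beta) - ridge/2 * ||beta_no_intercept||^2``; with
    ``ridge=0`` this is the exact maximum-likelihood fit (so the mean fitted
    score equals the observed exposure proportion).  Deterministic given its
    inputs.  Standard errors come from the inverse penalised Fisher
    information.
    """
    y = np.asarray(exposure, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design matrix and exposure length differ")
    n1 = int(y.sum())
    if n1 == 0 or n1 == len(y):
        raise EstimationError("exposure has a single class; cannot fit")
    if ridge < 0:
        raise ConfigurationError("ridge must be >= 0")

    if X.shape[1] == 0:  # degenerate spec: intercept-only model
        p_hat = n1 / len(y)
        eta = float(np.log(p_hat / (1 - p_hat)))
        scores = pd.Series(np.full(len(y), p_hat), index=X.index, name="score")
        se0 = math.sqrt(1.0 / (len(y) * p_hat * (1 - p_hat)))
        return PropensityFit(
            coefficients=pd.Series({"intercept": eta}),
            standard_errors=pd.Series({"intercept": se0}),
            scores=scores, converged=True, c_statistic=0.5,
            n_used=len(y), ridge=ridge)

    Xv = X.to_numpy(dtype=float)
    # standardise internally for lbfgs conditioning; coefficients are
    # back-transformed, so the ridge penalty acts on the standardised scale
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xv - mu) / sd
    C = (1.0 / ridge) if ridge > 0 else np.inf
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    model.fit(Xs, y)
    converged = int(model.n_iter_[0]) < 5000
    if not converged:
        raise EstimationError(
            f"logistic fit did not converge in {int(model.n_iter_[0])} "
            "iterations")

    coef = model.coef_[0] / sd
    intercept = model.intercept_[0] - float((model.coef_[0] * mu / sd).sum())
    beta = np.concatenate([[intercept], coef])
    names = ["intercept"] + list(X.columns)
    X1 = np.column_stack([np.ones(len(y)), Xv])
    eta = X1 @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = (X1 * w[:, None]).T @ X1
    if ridge > 0:
        pen = np.full(len(beta), ridge)
        pen[0] = 0.0
        info = info + np.diag(pen)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # singular information: SEs unavailable
        se = np.full(len(beta), np.nan)

    scores = pd.Series(np.clip(p, 1e-12, 1 - 1e-12), index=X.index,
                       name="score")
    return PropensityFit(
        coefficients=pd.Series(beta, index=names),
        standard_errors=pd.Series(se, index=names),
        scores=scores,
        converged=converged,
        c_statistic=c_statistic(scores.to_numpy(), y),
        n_used=len(y),
        ridge=ridge,
    )


def c_statistic(scores, exposure) -> float:
    """P(score of a random exposed > score of a random unexposed), ties half.

    Equivalent to the area under the ROC curve.
    """
    y = np.asarray(exposure, dtype=float)
    if y.min() == y.max():
        raise EstimationError("c-statistic needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))
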