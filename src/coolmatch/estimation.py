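"""Effect estimation with replication-combined uncertainty.

Each matching replication yields a point estimate and a within-replication
SE (arms treated as independent samples).  Across the ``m`` replications
the point estimates are averaged and the combined variance is

    SE^2 = W + (1 + 1/m) * B

where ``W`` is the mean squared within-replication SE and ``B`` the sample
variance of the replication estimates — the multiple-imputation-style
reading of combining within- and between-replication components.
Confidence intervals and p-values use the normal reference distribution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from coolmatch.config import EstimationError
from coolmatch.matching import MatchedPairSet

logger = logging.getLogger(__name__)

Z95 = 1.96

BINARY_OUTCOMES = [
    "culture_positive_loi", "pragmatic_loi", "pragmatic_nec", "severe_nec",
    "survived", "hypoglycaemia", "breastfeeding_at_discharge",
]
CONTINUOUS_OUTCOMES = [
    "length_of_stay", "central_line_days", "first_suckle_day",
    "first_maternal_milk_day", "discharge_weight_sds",
]


@dataclass
class EffectEstimate:
    outcome: str
    estimand: str            # "rate_difference_pp" | "odds_ratio" | "mean_difference"
    estimate: float          # OR on the natural scale; others on their own scale
    se: float                # log scale for the OR
    ci_low: float
    ci_high: float
    p: float
    W: float
    B: float
    m: int


# ---------------------------------------------------------------------------
# per-replication estimators
# ---------------------------------------------------------------------------

def rate_difference(x1: int, n1: int, x2: int, n2: int,
                    ) -> tuple[float, float]:
    """Percentage-point difference p1 - p2 and its SE (arm 1 = exposed)."""
    if n1 < 1 or n2 < 1:
        raise EstimationError("rate_difference needs n >= 1 in both arms")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("event counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    est = 100.0 * (p1 - p2)
    se = 100.0 * math.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    return est, se


def odds_ratio(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Odds ratio and the SE of its log (0.5 correction iff any cell is 0)."""
    if n1 < 1 or n2 < 1:
        raise EstimationError("odds_ratio needs n >= 1 in both arms")
    cells = [x1, n1 - x1, x2, n2 - x2]
    if (x1 == 0 and x2 == 0) or (x1 == n1 and x2 == n2):
        raise EstimationError("odds ratio undefined: no discordant outcomes")
    if any(c == 0 for c in cells):
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    or_ = (a * d) / (c * b)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, se_log


def mean_difference(values1, values2) -> tuple[float, float]:
    """Difference of arm means with the pooled-variance two-sample SE."""
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    v1 = v1[~np.isnan(v1)]
    v2 = v2[~np.isnan(v2)]
    if len(v1) < 2 or len(v2) < 2:
        raise EstimationError("mean_difference needs >= 2 values per arm")
    est = float(v1.mean() - v2.mean())
    sp2 = (((len(v1) - 1) * v1.var(ddof=1) + (len(v2) - 1) * v2.var(ddof=1))
           / (len(v1) + len(v2) - 2))
    se = math.sqrt(sp2 * (1 / len(v1) + 1 / len(v2)))
    return est, se


# ---------------------------------------------------------------------------
# replication combination
# ---------------------------------------------------------------------------

def combine_replications(estimates, ses, outcome: str = "",
                         estimand: str = "") -> EffectEstimate:
    """Combine m replication estimates into one estimate with SE/CI/p."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size < 1 or est.size != se.size:
        raise ValueError("need m >= 1 estimates with matching SEs")
    if not (np.isfinite(est).all() and np.isfinite(se).all()):
        raise ValueError("estimates and SEs must be finite")
    m = est.size
    point = float(est.mean())
    W = float((se ** 2).mean())
    if m == 1:
        logger.info("single replication: between-replication variance "
                    "undefined, using within-replication SE")
        B = 0.0
    elif est.max() == est.min():
        B = 0.0  # exact agreement: no between-replication component
    else:
        B = float(est.var(ddof=1))
    combined_se = math.sqrt(W + (1 + 1 / m) * B)
    ci_low, ci_high = point - Z95 * combined_se, point + Z95 * combined_se
    if combined_se == 0:
        p = 1.0 if point == 0 else np.nextafter(0, 1)
    else:
        p = float(2 * norm.sf(abs(point) / combined_se))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return EffectEstimate(outcome=outcome, estimand=estimand, estimate=point,
                          se=combined_se, ci_low=ci_low, ci_high=ci_high,
                          p=p, W=W, B=B, m=m)


def _combined_or(reps: list[tuple[float, float]], outcome: str,
                 ) -> EffectEstimate:
    """Combine odds ratios on the log scale, report on the natural scale."""
    logs = [math.log(o) for o, _ in reps]
    ses = [s for _, s in reps]
    c = combine_replications(logs, ses, outcome=outcome, estimand="odds_ratio")
    c.estimate = math.exp(c.estimate)
    c.ci_low, c.ci_high = math.exp(c.ci_low), math.exp(c.ci_high)
    return c


def estimate_effects(analysis: pd.DataFrame,
                     pair_sets: list[MatchedPairSet],
                     binary_outcomes: list[str] | None = None,
                     continuous_outcomes: list[str] | None = None,
                     ) -> pd.DataFrame:
    """Per-outcome combined effect estimates over all matching replications.

    Binary outcomes yield both a rate difference (percentage points) and an
    odds ratio; continuous outcomes yield a mean difference.  Outcomes whose
    per-replication estimator fails in any replication (e.g. an odds ratio
    with no events anywhere) are skipped with a warning.
    """
    binary_outcomes = BINARY_OUTCOMES if binary_outcomes is None \
        else binary_outcomes
    continuous_outcomes = CONTINUOUS_OUTCOMES if continuous_outcomes is None \
        else continuous_outcomes
    a = analysis.set_index("infant_id")
    rows = []
    for outcome in binary_outcomes:
        rd_reps, or_reps = [], []
        try:
            for ps in pair_sets:
                e = a.loc[ps.pairs["exposed_id"], outcome].astype(bool)
                u = a.loc[ps.pairs["unexposed_id"], outcome].astype(bool)
                rd_reps.append(rate_difference(int(e.sum()), len(e),
                                               int(u.sum()), len(u)))
                or_reps.append(odds_ratio(int(e.sum()), len(e),
                                          int(u.sum()), len(u)))
        except EstimationError as err:
            logger.warning("skipping %s: %s", outcome, err)
            continue
        rows.append(combine_replications([r[0] for r in rd_reps],
                                         [r[1] for r in rd_reps],
                                         outcome, "rate_difference_pp"))
        rows.append(_combined_or(or_reps, outcome))
    for outcome in continuous_outcomes:
        reps = []
        try:
            for ps in pair_sets:
                e = a.loc[ps.pairs["exposed_id"], outcome].astype(float)
                u = a.loc[ps.pairs["unexposed_id"], outcome].astype(float)
                reps.append(mean_difference(e, u))
        except EstimationError as err:
            logger.warning("skipping %s: %s", outcome, err)
            continue
        rows.append(combine_replications([r[0] for r in reps],
                                         [r[1] for r in reps],
                                         outcome, "mean_difference"))
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# trend and power
# ---------------------------------------------------------------------------

def exposure_trend(years, exposed_counts, totals) -> tuple[float, float]:
    """Linear-probability trend of exposure over calendar year.

    OLS of the individual binary exposure indicator on year; returns
    (slope per year in proportion units, two-sided p from the slope t-test).
    """
    years = np.asarray(years, dtype=float)
    exposed_counts = np.asarray(exposed_counts, dtype=int)
    totals = np.asarray(totals, dtype=int)
    if len(years) < 3:
        raise EstimationError("trend needs >= 3 distinct years")
    if (exposed_counts > totals).any() or (totals < 1).any():
        raise ValueError("invalid yearly counts")
    y = np.concatenate([
        np.repeat([1.0, 0.0], [x, n - x])
        for x, n in zip(exposed_counts, totals)
    ])
    x = np.repeat(years, totals)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def power_two_proportions(baseline: float, difference: float,
                          alpha: float = 0.05, power: float = 0.90,
                          ) -> dict:
    """Normal-approximation sample size for two independent proportions.

    Returns ``{"n_per_group": ..., "formula": ...}``; ``n_per_group`` is
    ``math.inf`` when the detectable difference is zero.
    """
    p1 = float(baseline)
    p2 = float(baseline) + float(difference)
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("proportions must lie strictly in (0, 1)")
    if power <= alpha:
        raise ValueError("power must exceed alpha")
    formula = ("n = (z_{1-a/2} sqrt(2 pbar qbar) + z_{1-b} "
               "sqrt(p1 q1 + p2 q2))^2 / (p1 - p2)^2, pooled-variance "
               "normal approximation")
    if difference == 0:
        return {"n_per_group": math.inf, "formula": formula}
    za = norm.isf(alpha / 2)
    zb = norm.isf(1 - power)
    pbar = (p1 + p2) / 2
    num = (za * math.sqrt(2 * pbar * (1 - pbar))
           + zb * math.sqrt(p1 * (1 - p1) + p2 * (1 - p2))) ** 2
    n = math.ceil(num / (p1 - p2) ** 2)
    return {"n_per_group": n, "formula": formula}
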