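"""Replicated 1:1 matching within exact strata and propensity deciles.

Infants are first grouped exactly by birth-year band (consecutive 2-year
windows of the study period) and arterial cord-pH band; within each group
they are split into propensity-score deciles; within each (stratum, decile)
cell exposed and unexposed infants are paired uniformly at random without
replacement until the minority side is exhausted.  Because pairing within a
cell is stochastic, the whole procedure is replicated ``m`` times with
derived seeds and results are averaged downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coolmatch.config import ConfigurationError, DataError

logger = logging.getLogger(__name__)

PH_BANDS = [">7.0", "6.9-7.0", "<6.9", "missing"]


def ph_band(value) -> str:
    """Band a numeric arterial cord pH: >7.0, 6.9-7.0 (closed), <6.9."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "missing"
    v = float(value)
    if v > 7.0:
        return ">7.0"
    if v >= 6.9:
        return "6.9-7.0"
    return "<6.9"


@dataclass
class MatchedPairSet:
    """One replication's pairs: columns exposed_id, unexposed_id, stratum,
    decile."""

    replication: int
    seed: int
    pairs: pd.DataFrame

    def __len__(self) -> int:
        return len(self.pairs)

    def all_ids(self) -> list:
        return (self.pairs["exposed_id"].tolist()
                + self.pairs["unexposed_id"].tolist())


def year_bands(year_range: tuple[int, int]) -> list[tuple[int, int]]:
    y0, y1 = year_range
    return [(y, min(y + 1, y1)) for y in range(y0, y1 + 1, 2)]


def assign_strata(analysis: pd.DataFrame,
                  year_range: tuple[int, int] = (2010, 2017),
                  include_missing_ph: bool = True) -> pd.Series:
    """Exact-matching stratum label per infant: "YYYY-YYYY|ph-band".

    With ``include_missing_ph`` (default) missing cord pH forms its own
    band, giving 4 x 4 = 16 cells over an 8-year period; without it the
    strict 4 x 3 = 12-cell grouping is used and missing-pH infants are
    labelled NA (excluded from matching).
    """
    years = analysis["birth_year"].astype(int)
    y0, y1 = year_range
    if (years < y0).any() or (years > y1).any():
        bad = years[(years < y0) | (years > y1)].iloc[0]
        raise ConfigurationError(
            f"birth year {bad} outside configured range {year_range}")
    bands = year_bands(year_range)
    starts = np.array([b[0] for b in bands])
    labels = np.array([f"{a}-{b}" for a, b in bands], dtype=object)
    band_lab = labels[np.searchsorted(starts, years.to_numpy(),
                                      side="right") - 1]

    ph = analysis["cord_ph_band"].astype(object).where(
        analysis["cord_ph_band"].notna(), "missing").astype(str)
    unknown = ~ph.isin(PH_BANDS)
    if unknown.any():
        raise DataError(f"unknown cord pH band {ph[unknown].iloc[0]!r}")
    stratum = pd.Series(band_lab, index=analysis.index) + "|" + ph
    if not include_missing_ph:
        stratum = stratum.where(ph != "missing")
    return stratum.rename("stratum")


def propensity_deciles(scores: pd.Series, strata: pd.Series,
                       n_bins: int = 10) -> pd.Series:
    """Decile label (0-based) per infant, computed within each stratum.

    Infants are ranked by score (ties kept together; ordering among
    distinct scores is by score then stable input order) and cut into
    ``min(n_bins, n)`` groups whose sizes differ by at most one when scores
    are distinct; tied scores always share a group.  Strata with fewer than
    ``n_bins`` infants get fewer groups (logged).
    """
    if ((scores <= 0) | (scores >= 1)).any():
        raise ValueError("propensity scores must lie strictly in (0, 1)")
    out = pd.Series(pd.NA, index=scores.index, dtype="Int64", name="decile")
    for stratum, idx in strata.dropna().groupby(strata.dropna()).groups.items():
        vals = scores.loc[idx]
        n = len(vals)
        k = min(n_bins, n)
        if k < n_bins:
            logger.info("stratum %s has %d infants; using %d groups",
                        stratum, n, k)
        order = np.argsort(vals.to_numpy(), kind="stable")
        rank = np.empty(n, dtype=int)
        rank[order] = np.arange(n)
        group = (rank * k) // n
        # tied scores take the group of their first occurrence
        v = vals.to_numpy()
        first_group: dict[float, int] = {}
        for pos in order:
            g = int(group[pos])
            if v[pos] in first_group:
                group[pos] = first_group[v[pos]]
            else:
                first_group[v[pos]] = g
        out.loc[idx] = group
    return out


def match_once(analysis: pd.DataFrame, strata: pd.Series, deciles: pd.Series,
               seed: int, replication: int = 1) -> MatchedPairSet:
    """One random 1:1 matching; pair count per cell = min(#exposed, #unexposed).

    Reproducible from ``seed``; infants with NA stratum or decile are
    ignored.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "infant_id": analysis["infant_id"].to_numpy(),
        "exposed": analysis["exposure_pn"].astype(bool).to_numpy(),
        "stratum": strata.to_numpy(),
        "decile": deciles.to_numpy(),
    }).dropna(subset=["stratum", "decile"])
    records = []
    for (stratum, decile), cell in df.groupby(["stratum", "decile"],
                                              observed=True, sort=True):
        exp_ids = np.sort(cell.loc[cell["exposed"], "infant_id"].to_numpy())
        une_ids = np.sort(cell.loc[~cell["exposed"], "infant_id"].to_numpy())
        k = min(len(exp_ids), len(une_ids))
        if k == 0:
            continue
        exp_pick = rng.permutation(exp_ids)[:k]
        une_pick = rng.permutation(une_ids)[:k]
        for e, u in zip(exp_pick, une_pick):
            records.append((e, u, stratum, int(decile)))
    pairs = pd.DataFrame(records, columns=["exposed_id", "unexposed_id",
                                           "stratum", "decile"])
    return MatchedPairSet(replication=replication, seed=seed, pairs=pairs)


def replicate_matching(analysis: pd.DataFrame, strata: pd.Series,
                       deciles: pd.Series, m: int = 25,
                       base_seed: int = 0) -> list[MatchedPairSet]:
    """``m`` independent matchings with seeds ``base_seed + r`` (r = 1..m).

    The pair count is identical across replications (it is fixed by the
    min-rule in each cell).
    """
    if m < 1:
        raise ConfigurationError(f"m must be >= 1, got {m}")
    return [match_once(analysis, strata, deciles, seed=base_seed + r,
                       replication=r) for r in range(1, m + 1)]


def _smd(x1: np.ndarray, x0: np.ndarray) -> float:
    m1, m0 = np.nanmean(x1), np.nanmean(x0)
    v1, v0 = np.nanvar(x1, ddof=1), np.nanvar(x0, ddof=1)
    pooled = np.sqrt((v1 + v0) / 2.0)
    if pooled == 0 or np.isnan(pooled):
        return 0.0 if np.isclose(m1, m0) else np.inf
    return float((m1 - m0) / pooled)


def _balance_columns(analysis: pd.DataFrame,
                     covariates: list[str]) -> pd.DataFrame:
    """Numeric view of covariates; categoricals expand to indicator columns."""
    cols = {}
    for name in covariates:
        col = analysis[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.astype(float)
        else:
            as_str = col.astype(object).where(col.notna(), "missing").astype(str)
            for lev in sorted(as_str.unique()):
                cols[f"{name}={lev}"] = (as_str == lev).astype(float)
    return pd.DataFrame(cols, index=analysis.index)


def balance_table(analysis: pd.DataFrame, pair_sets: list[MatchedPairSet],
                  covariates: list[str]) -> pd.DataFrame:
    """Standardised mean differences before and after matching.

    Post-match SMDs are averaged over replications.  Columns: ``covariate``,
    ``smd_pre``, ``smd_post``.
    """
    if not pair_sets:
        raise ValueError("at least one replication required")
    num = _balance_columns(analysis, covariates)
    num.index = analysis["infant_id"].to_numpy()
    exposed = analysis.set_index("infant_id")["exposure_pn"].astype(bool)

    pre = {c: _smd(num.loc[exposed, c].to_numpy(),
                   num.loc[~exposed, c].to_numpy()) for c in num.columns}
    post_acc = {c: [] for c in num.columns}
    for ps in pair_sets:
        e = num.loc[ps.pairs["exposed_id"].to_numpy()]
        u = num.loc[ps.pairs["unexposed_id"].to_numpy()]
        for c in num.columns:
            post_acc[c].append(_smd(e[c].to_numpy(), u[c].to_numpy()))
    return pd.DataFrame({
        "covariate": list(num.columns),
        "smd_pre": [pre[c] for c in num.columns],
        "smd_post": [float(np.mean(post_acc[c])) for c in num.columns],
    })
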