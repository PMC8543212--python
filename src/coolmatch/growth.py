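"""Synthetic weight-for-age growth reference.

A deliberately small mean/SD table by sex and postmenstrual week, used both
to draw discharge weights in the synthetic cohort and to convert weights to
SD scores (z-scores) downstream, so the round trip is exactly invertible in
tests.  It is a synthetic stand-in: real weight-for-age standards are out of
scope for this package.
"""

from __future__ import annotations

import numpy as np

MIN_WEEK = 34
MAX_WEEK = 52


def _mean_g(week: np.ndarray, male: np.ndarray) -> np.ndarray:
    # ~190 g/week up to 42 weeks, slowing after; boys ~120 g heavier
    w = np.clip(week, MIN_WEEK, MAX_WEEK).astype(float)
    base = 3500.0 + 190.0 * np.minimum(w - 40.0, 2.0) + 120.0 * np.maximum(w - 42.0, 0.0)
    return base + 120.0 * np.asarray(male, dtype=float) - 60.0


def _sd_g(week: np.ndarray) -> np.ndarray:
    w = np.clip(week, MIN_WEEK, MAX_WEEK).astype(float)
    return 420.0 + 8.0 * (w - 40.0)


def reference_mean_sd(male, week) -> tuple[np.ndarray, np.ndarray]:
    """Reference mean and SD (grams) for ``male`` (0/1) at ``week`` (PMA)."""
    male = np.asarray(male)
    week = np.asarray(week)
    return _mean_g(week, male), _sd_g(week)


def weight_to_sds(weight_g, male, week) -> np.ndarray:
    """Convert weight (g) to an SD score against the synthetic reference."""
    mean, sd = reference_mean_sd(male, week)
    return (np.asarray(weight_g, dtype=float) - mean) / sd


def sds_to_weight(sds, male, week) -> np.ndarray:
    """Inverse of :func:`weight_to_sds`."""
    mean, sd = reference_mean_sd(male, week)
    return mean + np.asarray(sds, dtype=float) * sd
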