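"""Bioanalytical method-validation statistics and tissue-recovery summaries.

Covers straight-line calibration (acceptance at R^2 > 0.99), repeatability
(mean/SD/RSD of replicate injections), accuracy as percent recovery against
nominal (80-120% acceptance band), signal-to-noise based detection and
quantification limits (S/N 3 and 10), an exact two-sided Mann-Whitney U test
by full enumeration for small groups, and median (min, max) tissue summaries.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationFit",
    "fit_calibration",
    "repeatability",
    "accuracy",
    "accuracy_summary",
    "lod_loq",
    "tissue_compare",
    "tissue_summary",
    "ACCURACY_BAND",
    "R2_PASS",
]

logger = logging.getLogger(__name__)

R2_PASS = 0.99
ACCURACY_BAND = (80.0, 120.0)
#: Exhaustive enumeration is used for the exact U test up to this pooled size.
EXACT_N_MAX = 12


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercept: float
    r_squared: float
    passes: bool


def fit_calibration(levels, signals) -> CalibrationFit:
    """Least-squares straight line of signal vs nominal concentration."""
    levels = np.asarray(levels, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if levels.shape != signals.shape or levels.ndim != 1:
        raise ValueError("levels and signals must be 1-D arrays of equal length")
    if len(np.unique(levels)) < 3:
        raise ValueError("calibration needs at least 3 distinct levels")
    res = stats.linregress(levels, signals)
    r2 = float(res.rvalue**2)
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        passes=r2 > R2_PASS,
    )


def repeatability(signals) -> tuple[float, float, float]:
    """Replicate mean, sample SD (n-1 denominator) and RSD% (100*SD/mean)."""
    signals = np.asarray(signals, dtype=float)
    if len(signals) < 2:
        raise ValueError("repeatability needs at least 2 replicates")
    mean = float(signals.mean())
    sd = float(signals.std(ddof=1))
    if mean == 0.0:
        raise ZeroDivisionError("RSD undefined for zero mean")
    return mean, sd, 100.0 * sd / mean


def rsd_from_summary(mean: float, sd: float) -> float:
    """RSD% directly from a reported mean and SD."""
    if mean == 0.0:
        raise ZeroDivisionError("RSD undefined for zero mean")
    return 100.0 * sd / mean


def accuracy(back_calculated, nominal) -> np.ndarray:
    """Percent recovery of back-calculated vs nominal concentrations."""
    back = np.asarray(back_calculated, dtype=float)
    nominal = np.asarray(nominal, dtype=float)
    if np.any(nominal <= 0):
        raise ValueError("nominal concentrations must be > 0")
    return 100.0 * back / nominal


def accuracy_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-level recovery summary (mean/SD/RSD and the 80-120% band verdict).

    ``table`` needs columns ``level_ppb`` and ``recovery_pct``.
    """
    lo, hi = ACCURACY_BAND
    rows = []
    for level, group in table.groupby("level_ppb"):
        values = group["recovery_pct"].to_numpy(dtype=float)
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if len(values) > 1 else np.nan
        rows.append(
            {
                "level_ppb": level,
                "n": len(values),
                "mean": mean,
                "sd": sd,
                "rsd_pct": 100.0 * sd / mean if len(values) > 1 else np.nan,
                "passes": bool(lo <= mean <= hi),
            }
        )
    return pd.DataFrame(rows)


def lod_loq(signal_height: float, noise_height: float, conc: float) -> tuple[float, float]:
    """Detection and quantification limits from one chromatogram's S/N.

    Assumes a linear signal-concentration relation: LOD is the concentration
    at S/N = 3, LOQ at S/N = 10.
    """
    if noise_height <= 0:
        raise ValueError("noise height must be > 0")
    sn = signal_height / noise_height
    if sn <= 0:
        raise ValueError("signal-to-noise must be > 0")
    return 3.0 * conc / sn, 10.0 * conc / sn


def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def tissue_compare(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; exact by full enumeration of rank
    assignments (mid-ranks for ties) when the pooled size is <= 12, else the
    continuity-corrected normal approximation.

    Returns ``(U, p)`` where U counts pairs won by ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 1 or n_b < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # mid-ranks on ties
    u_obs = _u_statistic(ranks[:n_a], n_a, n_b)
    if np.all(pooled == pooled[0]):
        return u_obs, 1.0
    if n_a + n_b <= EXACT_N_MAX:
        center = n_a * n_b / 2.0
        dev_obs = abs(u_obs - center)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n_a + n_b), n_a):
            u = _u_statistic(ranks[list(combo)], n_a, n_b)
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                count += 1
        return u_obs, count / total
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def tissue_summary(table: pd.DataFrame, reference: str = "plasma") -> pd.DataFrame:
    """Median (min, max) per tissue plus the reference/tissue median ratio.

    ``table`` needs columns ``tissue`` and ``conc_ug_g``.
    """
    rows = []
    medians = {}
    for tissue, group in table.groupby("tissue"):
        values = group["conc_ug_g"].to_numpy(dtype=float)
        medians[tissue] = float(np.median(values))
        rows.append(
            {
                "tissue": tissue,
                "n": len(values),
                "median": medians[tissue],
                "min": float(values.min()),
                "max": float(values.max()),
            }
        )
    out = pd.DataFrame(rows)
    ref = medians.get(reference)
    if ref is not None:
        out["reference_ratio"] = ref / out["median"]
    return out
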