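"""Non-compartmental analysis of single-dose concentration-time profiles.

Per profile: terminal-slope regression (best adjusted R^2 over contiguous
terminal subsets), linear-log trapezoidal areas, first-moment areas with
analytic tails, clearance/volume terms, and absolute bioavailability from
dose-normalized AUC ratios.  A study-level summary mirrors the usual
"mean +/- SD, Tmax as median (range)" reporting shape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LambdaZFit",
    "NCAResult",
    "fit_lambda_z",
    "half_life",
    "auc_linlog",
    "auc_extrapolate",
    "moments_and_volumes",
    "bioavailability",
    "nca_profile",
    "run_nca",
    "nca_summary",
]

logger = logging.getLogger(__name__)

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result."""

    lambda_z: float
    n_points: int
    r2_adj: float
    slope: float
    intercept: float  # of ln(conc) vs time
    status: str = "ok"  # ok | too_few_points | non_negative_slope

    def conc_at(self, t: float) -> float:
        """Regression-predicted concentration at time t."""
        return float(np.exp(self.intercept + self.slope * t))


@dataclass
class NCAResult:
    """Per-profile non-compartmental parameter set."""

    subject_id: object
    route: str
    status: str = "ok"
    lambda_z: float = np.nan
    t_half_z: float = np.nan
    n_points_lambda_z: int = 0
    r2_adj: float = np.nan
    auc_t: float = np.nan
    auc_inf: float = np.nan
    auc_extrap_pct: float = np.nan
    aumc: float = np.nan
    mrt: float = np.nan
    cmax: float = np.nan
    tmax: float = np.nan
    cmax_over_auc: float = np.nan
    cl: float = np.nan
    vss: float = np.nan
    vdarea: float = np.nan
    vi: float = np.nan
    f_pct: float = np.nan

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def half_life(k: float) -> float:
    """ln(2)/k; the exact natural-log constant is used, not the rounded 0.693."""
    if not k > 0:
        raise ValueError(f"rate constant must be > 0, got {k!r}")
    return _LN2 / k


def _adjusted_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on x; returns (slope, intercept, adjusted R^2)."""
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(slope), float(intercept), float(r2_adj)


def fit_lambda_z(
    times, concs, min_points: int = 3, exclude_cmax: bool = True
) -> LambdaZFit:
    """Terminal elimination rate constant from the semilog profile.

    All contiguous terminal subsets of at least ``min_points`` observations
    strictly after Tmax (Cmax itself excluded when ``exclude_cmax``) are
    regressed on the log scale and the subset with the best adjusted R^2 wins.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if times.shape != concs.shape or times.ndim != 1:
        raise ValueError("times and concs must be 1-D arrays of equal length")
    keep = concs > 0
    times, concs = times[keep], concs[keep]
    if len(times) == 0:
        return LambdaZFit(np.nan, 0, np.nan, np.nan, np.nan, "too_few_points")
    i_max = int(np.argmax(concs))  # earliest maximum on ties
    start = i_max + 1 if exclude_cmax else i_max
    t_term, c_term = times[start:], concs[start:]
    if len(t_term) < min_points:
        return LambdaZFit(np.nan, 0, np.nan, np.nan, np.nan, "too_few_points")
    log_c = np.log(c_term)
    best: Optional[tuple[float, float, float, int]] = None
    for first in range(0, len(t_term) - min_points + 1):
        slope, intercept, r2_adj = _adjusted_r2(t_term[first:], log_c[first:])
        if best is None or r2_adj > best[2] + 1e-12:
            best = (slope, intercept, r2_adj, len(t_term) - first)
    slope, intercept, r2_adj, n_used = best
    if slope >= 0:
        logger.warning("terminal slope is non-negative; lambda_z flagged")
        return LambdaZFit(np.nan, n_used, r2_adj, slope, intercept, "non_negative_slope")
    return LambdaZFit(-slope, n_used, r2_adj, slope, intercept, "ok")


def auc_linlog(times, concs) -> float:
    """Linear-log ("linear up / log down") trapezoidal AUC over the samples.

    Linear rule on non-decreasing intervals; logarithmic rule
    ``dt*(C1-C2)/ln(C1/C2)`` on strictly decreasing intervals with positive
    endpoints; non-positive endpoints fall back to the linear rule.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if times.ndim != 1 or times.shape != concs.shape:
        raise ValueError("times and concs must be 1-D arrays of equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    total = 0.0
    for (t1, t2), (c1, c2) in zip(
        zip(times[:-1], times[1:]), zip(concs[:-1], concs[1:])
    ):
        dt = t2 - t1
        if c2 < c1 and c1 > 0 and c2 > 0:
            total += dt * (c1 - c2) / math.log(c1 / c2)
        else:
            if c2 < c1:  # declining into a non-positive value
                logger.warning(
                    "non-positive concentration on a declining interval; "
                    "using the linear rule"
                )
            total += dt * 0.5 * (c1 + c2)
    return total


def auc_extrapolate(
    auc_t: float, c_last_pred: float, lambda_z: float
) -> tuple[float, float]:
    """AUC to infinity and the extrapolated percentage.

    The tail is ``c_last_pred / lambda_z`` with ``c_last_pred`` taken from the
    terminal regression line at the last sampling time.
    """
    if not lambda_z > 0:
        raise ValueError("lambda_z must be > 0")
    if c_last_pred < 0:
        raise ValueError("c_last_pred must be >= 0")
    tail = c_last_pred / lambda_z
    auc_inf = auc_t + tail
    if auc_inf == 0.0:
        return 0.0, np.nan
    extrap_pct = 100.0 * tail / auc_inf
    if auc_t == 0.0 and tail > 0.0:
        logger.warning("AUC_t is zero; 100%% extrapolation is degenerate")
    return auc_inf, extrap_pct


def _back_extrapolated_c0(times: np.ndarray, concs: np.ndarray) -> float:
    """C(0) from the log-linear extension of the first two positive samples."""
    pos = concs > 0
    t, c = times[pos], concs[pos]
    if len(t) < 2 or c[1] >= c[0]:
        return float(c[0]) if len(t) else np.nan
    slope = (math.log(c[1]) - math.log(c[0])) / (t[1] - t[0])
    return float(c[0] * math.exp(-slope * t[0]))


def moments_and_volumes(
    times,
    concs,
    dose: float,
    lz: LambdaZFit,
    auc_inf: float,
    bw: float | None = None,
) -> dict:
    """First-moment area, MRT and the clearance/volume terms of an IV profile.

    AUMC uses the same linear-log rule applied to ``t*C(t)`` plus the analytic
    tail ``Cpred*t_last/lz + Cpred/lz^2``; ``Vi`` divides the dose by the
    back-extrapolated first concentration.  With ``bw`` given, clearance and
    volumes are additionally reported per kg.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    t_last = times[-1]
    c_pred = lz.conc_at(t_last)
    aumc_t = auc_linlog(times, times * concs)
    aumc = aumc_t + c_pred * t_last / lz.lambda_z + c_pred / lz.lambda_z**2
    mrt = aumc / auc_inf
    cl = dose / auc_inf
    vss = cl * mrt
    vdarea = dose / (auc_inf * lz.lambda_z)
    c0 = _back_extrapolated_c0(times, concs)
    vi = dose / c0 if c0 and c0 > 0 else np.nan
    out = {"aumc": aumc, "mrt": mrt, "cl": cl, "vss": vss, "vdarea": vdarea, "vi": vi}
    if bw:
        out.update(
            cl_per_kg=cl / bw, vss_per_kg=vss / bw,
            vdarea_per_kg=vdarea / bw, vi_per_kg=vi / bw,
        )
    return out


def bioavailability(
    auc_im: float, dose_im: float, auc_iv: float, dose_iv: float
) -> float:
    """Absolute bioavailability (%) from dose-normalized AUC ratios."""
    for name, value in (
        ("auc_im", auc_im), ("dose_im", dose_im),
        ("auc_iv", auc_iv), ("dose_iv", dose_iv),
    ):
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")
    return 100.0 * (auc_im / dose_im) / (auc_iv / dose_iv)


def nca_profile(
    times,
    concs,
    dose: float,
    route: str = "iv",
    subject_id: object = None,
    bw: float | None = None,
    min_points: int = 3,
) -> NCAResult:
    """Full NCA of one single-dose profile.

    For the extravascular route a (0, 0) anchor is prepended for the area
    computations; clearance and volume terms are only populated for IV.
    """
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    route = str(route).lower()
    res = NCAResult(subject_id=subject_id, route=route)

    i_max = int(np.argmax(concs))
    res.cmax = float(concs[i_max])
    res.tmax = float(times[i_max])

    lz = fit_lambda_z(times, concs, min_points=min_points, exclude_cmax=True)
    if lz.status != "ok":
        res.status = lz.status
        return res
    res.lambda_z = lz.lambda_z
    res.t_half_z = half_life(lz.lambda_z)
    res.n_points_lambda_z = lz.n_points
    res.r2_adj = lz.r2_adj

    if route == "im" and times[0] > 0:
        a_times = np.concatenate(([0.0], times))
        a_concs = np.concatenate(([0.0], concs))
    else:
        a_times, a_concs = times, concs
    res.auc_t = auc_linlog(a_times, a_concs)
    c_last_pred = lz.conc_at(times[-1])
    res.auc_inf, res.auc_extrap_pct = auc_extrapolate(res.auc_t, c_last_pred, lz.lambda_z)
    res.cmax_over_auc = res.cmax / res.auc_inf

    if route == "iv":
        per_kg = moments_and_volumes(a_times, a_concs, dose, lz, res.auc_inf, bw=bw)
        res.aumc = per_kg["aumc"]
        res.mrt = per_kg["mrt"]
        if bw:
            res.cl = per_kg["cl_per_kg"]
            res.vss = per_kg["vss_per_kg"]
            res.vdarea = per_kg["vdarea_per_kg"]
            res.vi = per_kg["vi_per_kg"]
        else:
            res.cl = per_kg["cl"]
            res.vss = per_kg["vss"]
            res.vdarea = per_kg["vdarea"]
            res.vi = per_kg["vi"]
    return res


def run_nca(
    events: pd.DataFrame, route: str = "both", per_kg: bool = False
) -> pd.DataFrame:
    """Per-subject NCA over an event table (see :mod:`pkcross.datagen`).

    The generative parameters are never consulted: only observed rows
    (EVID == 0) and dose rows (EVID == 1) are read.  IM bioavailability is
    computed per subject against the same subject's IV AUC when both routes
    are present.
    """
    route = route.lower()
    if route not in ("iv", "im", "both"):
        raise ValueError("route must be 'iv', 'im' or 'both'")
    wanted = {"iv": [1], "im": [2], "both": [1, 2]}[route]
    results: list[NCAResult] = []
    iv_norm: dict[object, float] = {}
    for (subject, route_code), group in events.groupby(["ID", "ROUTE"], sort=True):
        if route_code not in (1, 2):
            continue
        obs = group[group["EVID"] == 0].sort_values("TIME")
        dose_rows = group[group["EVID"] == 1]
        if dose_rows.empty or obs.empty:
            continue
        dose = float(dose_rows["AMT"].sum())
        bw = float(group["BW"].iloc[0]) if "BW" in group else None
        res = nca_profile(
            obs["TIME"].to_numpy(),
            obs["DV"].to_numpy(),
            dose=dose,
            route="iv" if route_code == 1 else "im",
            subject_id=subject,
            bw=bw if per_kg else None,
        )
        if route_code == 1 and res.status == "ok":
            iv_norm[subject] = res.auc_inf / dose
        if route_code in wanted:
            if route_code == 2 and res.status == "ok":
                res._dose_norm = res.auc_inf / dose  # stashed for the F pass
            results.append(res)
    for res in results:
        if res.route == "im" and res.status == "ok" and res.subject_id in iv_norm:
            res.f_pct = 100.0 * res._dose_norm / iv_norm[res.subject_id]
    table = pd.DataFrame([r.as_dict() for r in results])
    return table


_SUMMARY_PARAMS = [
    "lambda_z", "t_half_z", "auc_t", "auc_inf", "auc_extrap_pct", "aumc",
    "mrt", "cmax", "cmax_over_auc", "cl", "vss", "vdarea", "vi", "f_pct",
]


def nca_summary(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD per route; Tmax reported as median (min, max)."""
    rows = []
    for route, group in per_subject.groupby("route"):
        ok = group[group["status"] == "ok"]
        for param in _SUMMARY_PARAMS:
            values = ok[param].dropna()
            if values.empty:
                continue
            rows.append(
                {
                    "route": route,
                    "parameter": param,
                    "n": len(values),
                    "mean": values.mean(),
                    "sd": values.std(ddof=1) if len(values) > 1 else np.nan,
                }
            )
        tmax = ok["tmax"].dropna()
        if not tmax.empty:
            rows.append(
                {
                    "route": route,
                    "parameter": "tmax",
                    "n": len(tmax),
                    "median": tmax.median(),
                    "min": tmax.min(),
                    "max": tmax.max(),
                }
            )
    return pd.DataFrame(rows)
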