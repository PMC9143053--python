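"""Model evaluation: visual predictive check and nonparametric bootstrap."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .nlme import (
    PARAM_NAMES,
    FitResult,
    PopulationModel,
    StackedData,
    _mu_matrix,
    _predict,
    _residual_sd,
    fit_population,
    stack_events,
)

__all__ = ["VPCSummary", "vpc", "simulate_from_fit", "BootstrapResult", "bootstrap"]

logger = logging.getLogger(__name__)


@dataclass
class VPCSummary:
    """Observed percentiles per route/time bin with simulated confidence bands."""

    table: pd.DataFrame
    n_replicates: int
    pi: float
    ci: float

    def coverage(self) -> float:
        """Fraction of observed percentile points inside their simulated CI."""
        t = self.table
        inside = 0
        total = 0
        for q in ("lo", "med", "hi"):
            total += len(t)
            inside += int(
                (
                    (t[f"obs_{q}"] >= t[f"sim_{q}_ci_lower"])
                    & (t[f"obs_{q}"] <= t[f"sim_{q}_ci_upper"])
                ).sum()
            )
        return inside / total if total else np.nan


def _fit_mu_matrix(fit: FitResult, data: StackedData) -> np.ndarray:
    x = np.zeros(data.n_subjects)
    if fit.covariate_model != "none":
        x = np.log(data.bw / fit.ref_bw)
    return _mu_matrix(fit.mu, x, fit.exponents, fit.covariate_model)


def simulate_from_fit(
    fit: FitResult, data: StackedData, rng: np.random.Generator
) -> np.ndarray:
    """One replicate dataset (n, m) at the estimates: new etas + residuals."""
    omega = np.array([fit.omega_sd[name] for name in PARAM_NAMES])
    mu_i = _fit_mu_matrix(fit, data)
    eta = rng.standard_normal((data.n_subjects, len(PARAM_NAMES))) * omega
    f = _predict(mu_i + eta, data, fit.tlag)
    sd = _residual_sd(f, fit.sigma_prop, fit.sigma_add, fit.residual_error)
    return f + sd * rng.standard_normal(f.shape)


def vpc(
    fit: FitResult,
    data: pd.DataFrame | StackedData,
    n_replicates: int = 1000,
    seed: int = 0,
    pi: float = 0.95,
    ci: float = 0.975,
) -> VPCSummary:
    """Visual predictive check against the original sampling design.

    Time bins are the design's nominal sampling times per route (sparse fixed
    schedule, no binning algorithm).  For each bin the observed
    median/lower/upper percentile of the ``pi`` prediction interval is
    compared with the ``ci`` confidence interval of the same percentile
    across ``n_replicates`` simulated datasets.  The interval width is
    parameterized because published analyses quote both 90% and 95%
    conventions; the default is 95%.
    """
    if n_replicates < 100:
        logger.warning("fewer than 100 replicates gives unstable percentile CIs")
    stacked = data if isinstance(data, StackedData) else stack_events(data)
    rng = np.random.default_rng(seed)
    q_lo, q_hi = 100.0 * (1.0 - pi) / 2.0, 100.0 * (1.0 + pi) / 2.0
    ci_lo, ci_hi = 100.0 * (1.0 - ci) / 2.0, 100.0 * (1.0 + ci) / 2.0

    # group observation slots by (route, nominal time)
    bins: dict[tuple[int, float], tuple[np.ndarray, np.ndarray]] = {}
    for route_code, route_mask in ((1, stacked.is_iv), (2, ~stacked.is_iv)):
        sel = stacked.mask & route_mask
        times = np.unique(stacked.t[sel])
        for t_nom in times:
            where = sel & np.isclose(stacked.t, t_nom)
            bins[(route_code, float(t_nom))] = np.nonzero(where)

    sims = np.empty((n_replicates,) + stacked.y.shape)
    for r in range(n_replicates):
        sims[r] = simulate_from_fit(fit, stacked, rng)

    rows = []
    for (route_code, t_nom), idx in sorted(bins.items()):
        obs = stacked.y[idx]
        sim = sims[:, idx[0], idx[1]]  # (reps, n_in_bin)
        obs_q = np.percentile(obs, [q_lo, 50.0, q_hi])
        sim_q = np.percentile(sim, [q_lo, 50.0, q_hi], axis=1)  # (3, reps)
        row = {
            "route": "iv" if route_code == 1 else "im",
            "time_h": t_nom,
            "n_obs": len(obs),
            "obs_lo": obs_q[0],
            "obs_med": obs_q[1],
            "obs_hi": obs_q[2],
        }
        for name, values in zip(("lo", "med", "hi"), sim_q):
            row[f"sim_{name}_ci_lower"] = np.percentile(values, ci_lo)
            row[f"sim_{name}_median"] = np.percentile(values, 50.0)
            row[f"sim_{name}_ci_upper"] = np.percentile(values, ci_hi)
        rows.append(row)
    table = pd.DataFrame(rows)
    for name in ("lo", "med", "hi"):
        bad = table[f"sim_{name}_ci_lower"] > table[f"sim_{name}_ci_upper"]
        assert not bad.any()
    return VPCSummary(table=table, n_replicates=n_replicates, pi=pi, ci=ci)


@dataclass
class BootstrapResult:
    percentiles: pd.DataFrame
    estimates: pd.DataFrame
    n_boot: int
    n_failed: int
    success_rate: float
    reliable: bool


def bootstrap(
    data: pd.DataFrame | StackedData,
    model: PopulationModel,
    n_boot: int,
    seed: int = 0,
    method: str = "LAPLACE",
    max_iter: Optional[object] = None,
    resample: bool = True,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects with replacement and refit.

    Deterministic (LAPLACE) refits are the default for speed.  Failed refits
    are excluded and counted; a success rate below 50% flags the result as
    unreliable.  ``resample=False`` refits the identical subject set (used
    for identity checks).
    """
    stacked = data if isinstance(data, StackedData) else stack_events(data)
    if stacked.n_subjects < 2:
        raise ValueError("bootstrap needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    rows = []
    n_failed = 0
    for b in range(n_boot):
        if resample:
            idx = rng.integers(0, stacked.n_subjects, size=stacked.n_subjects)
        else:
            idx = np.arange(stacked.n_subjects)
        sample = stacked.subset(idx)
        try:
            fit = fit_population(
                sample, model, method=method, seed=seed + 1000 + b,
                max_iter=max_iter, compute_mofv=False, nm_restart=False,
            )
        except Exception as exc:  # noqa: BLE001 - replicate failures are data
            logger.warning("bootstrap replicate %d failed: %s", b, exc)
            n_failed += 1
            continue
        if fit.status == "failed":
            n_failed += 1
            continue
        row = {"replicate": b, **{k: v for k, v in fit.theta.as_dict().items()}}
        for name, fixed in fit.omega_fixed.items():
            if not fixed:
                row[f"omega_{name}"] = fit.omega_sd[name]
        row["sigma_prop"] = fit.sigma_prop
        row["sigma_add"] = fit.sigma_add
        rows.append(row)
    estimates = pd.DataFrame(rows)
    success_rate = len(rows) / n_boot if n_boot else 0.0
    reliable = success_rate >= 0.5
    if not reliable:
        logger.warning("bootstrap success rate %.0f%% < 50%%; flagged unreliable",
                       100 * success_rate)
    pct_rows = []
    for col in estimates.columns:
        if col == "replicate":
            continue
        values = estimates[col].dropna()
        if values.empty:
            continue
        pct_rows.append(
            {
                "parameter": col,
                "p2.5": np.percentile(values, 2.5),
                "p50": np.percentile(values, 50.0),
                "p97.5": np.percentile(values, 97.5),
            }
        )
    return BootstrapResult(
        percentiles=pd.DataFrame(pct_rows),
        estimates=estimates,
        n_boot=n_boot,
        n_failed=n_failed,
        success_rate=success_rate,
        reliable=reliable,
    )
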