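"""Synthetic study generator.

Produces virtual IV-then-IM crossover studies with the statistical structure
assumed by the downstream analyses (log-normal between-subject variability
shared across occasions, proportional residual error), plus bioanalytical
calibration/replicate tables and endpoint tissue-concentration tables.

The event-table dialect follows common population-PK tooling:

==========  =====================================================
column      meaning
==========  =====================================================
ID          subject number (1-based)
OCC         occasion (1 = first period IV, 2 = second period IM)
TIME        hours since the occasion's dose
AMT         dose amount (mg) on dose rows, 0 otherwise
DV          observed concentration (ug/mL); empty on dose rows
EVID        1 = dose, 0 = observation, 2 = pre-dose blank sample
ROUTE       1 = IV bolus (central), 2 = IM (depot)
BW          bodyweight (kg)
==========  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ThetaFixed, first_order_abs_conc, iv_bolus_conc

__all__ = [
    "IV_TIMES",
    "IM_TIMES",
    "StudyDesign",
    "GenerativeModel",
    "generate_study",
    "drop_observations",
    "generate_calibration",
    "generate_tissue",
]

PARAM_NAMES = ("cl", "vc", "cld", "vp", "ka", "f")

#: Default sampling grids (h): 0.5 min, 15 min, 30 min, 1, 2, 4, 6, 8, 24 h,
#: with one extra 48 h sample after the IM dose.
IV_TIMES = (0.5 / 60.0, 0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 24.0)
IM_TIMES = IV_TIMES + (48.0,)


@dataclass(frozen=True)
class StudyDesign:
    """Crossover sampling design: every subject gets IV then IM."""

    n_subjects: int = 4
    bw_range: tuple[float, float] = (25.0, 50.0)
    dose_per_kg: float = 4.0
    iv_times: tuple[float, ...] = IV_TIMES
    im_times: tuple[float, ...] = IM_TIMES
    washout_h: float = 168.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0 < self.bw_range[0] <= self.bw_range[1]):
            raise ValueError(f"invalid bodyweight range {self.bw_range!r}")
        if self.dose_per_kg <= 0:
            raise ValueError("dose_per_kg must be > 0")
        for name in ("iv_times", "im_times"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
                raise ValueError(f"{name} must be strictly increasing and > 0")


@dataclass(frozen=True)
class GenerativeModel:
    """Population-level generative truth for the simulator.

    ``omega_sd`` holds the log-scale SDs of the parameters with explicit
    between-subject variability; every other structural parameter gets
    ``fixed_omega_sd`` (default 15% CV).  Individual parameters are
    ``typical * exp(eta)`` with one eta vector per subject shared across both
    crossover occasions.  Observations carry proportional noise
    ``y = f * (1 + eps)``, ``eps ~ N(0, sigma_prop^2)``.
    """

    theta: ThetaFixed
    omega_sd: Mapping[str, float] = field(default_factory=dict)
    fixed_omega_sd: float = 0.15
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        for key, value in self.omega_sd.items():
            if key not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {key!r} in omega_sd")
            if value < 0:
                raise ValueError("omega_sd entries must be >= 0")
        if self.fixed_omega_sd < 0:
            raise ValueError("fixed_omega_sd must be >= 0")
        if self.sigma_prop < 0:
            raise ValueError("sigma_prop must be >= 0")
        if self.sigma_prop >= 1.0:
            raise ValueError(
                "sigma_prop >= 1 would make negative concentrations likely; refusing"
            )

    def sd_for(self, name: str) -> float:
        return float(self.omega_sd.get(name, self.fixed_omega_sd))

    @classmethod
    def reference(cls) -> "GenerativeModel":
        """Reference parameter set used throughout examples and tests:
        final-model typical values with estimated IIV on CL/Vc/Ka (33.17,
        33.47 and 95.86% CV), 15% CV elsewhere, 24.23% proportional error."""
        return cls(
            theta=ThetaFixed(cl=0.255, vc=7.11, cld=127.0, vp=2.51, ka=0.471, f=0.908),
            omega_sd={"cl": 0.3317, "vc": 0.3347, "ka": 0.9586},
            fixed_omega_sd=0.15,
            sigma_prop=0.2423,
        )


def _individual_params(
    gen: GenerativeModel, eta: np.ndarray
) -> dict[str, np.ndarray]:
    typical = gen.theta.as_dict()
    return {
        name: typical[name] * np.exp(eta[:, j]) for j, name in enumerate(PARAM_NAMES)
    }


def _noisy_obs(
    f: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Proportional noise, redrawing the rare eps <= -1 draws so DV > 0."""
    if sigma == 0.0:
        return f.copy()
    eps = rng.normal(0.0, sigma, size=f.shape)
    for _ in range(100):
        bad = eps <= -1.0
        if not np.any(bad):
            break
        eps[bad] = rng.normal(0.0, sigma, size=int(bad.sum()))
    return f * (1.0 + eps)


def generate_study(
    design: StudyDesign, gen: GenerativeModel, seed: int
) -> pd.DataFrame:
    """Simulate a crossover study; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    bw = rng.uniform(design.bw_range[0], design.bw_range[1], size=n)
    sds = np.array([gen.sd_for(name) for name in PARAM_NAMES])
    eta = rng.normal(0.0, 1.0, size=(n, len(PARAM_NAMES))) * sds
    params = _individual_params(gen, eta)
    doses = design.dose_per_kg * bw

    rows: list[dict] = []
    for i in range(n):
        for occ, route_code, times in (
            (1, 1, design.iv_times),
            (2, 2, design.im_times),
        ):
            common = {"ID": i + 1, "OCC": occ, "ROUTE": route_code, "BW": bw[i]}
            rows.append(
                {**common, "TIME": 0.0, "AMT": 0.0, "DV": 0.0, "EVID": 2}
            )
            rows.append(
                {**common, "TIME": 0.0, "AMT": doses[i], "DV": np.nan, "EVID": 1}
            )
            t = np.asarray(times, dtype=float)
            if route_code == 1:
                f_pred = iv_bolus_conc(
                    params["cl"][i], params["vc"][i], params["cld"][i],
                    params["vp"][i], doses[i], t,
                )
            else:
                f_pred = first_order_abs_conc(
                    params["cl"][i], params["vc"][i], params["cld"][i],
                    params["vp"][i], params["ka"][i], params["f"][i], doses[i], t,
                )
            dv = _noisy_obs(f_pred, gen.sigma_prop, rng)
            for time, value in zip(t, dv):
                rows.append(
                    {**common, "TIME": time, "AMT": 0.0, "DV": value, "EVID": 0}
                )
    table = pd.DataFrame(rows, columns=["ID", "OCC", "TIME", "AMT", "DV", "EVID", "ROUTE", "BW"])
    return table


def drop_observations(table: pd.DataFrame, indices: Sequence[int]) -> pd.DataFrame:
    """Drop observation rows by position among EVID==0 rows (0-based).

    Utility for mimicking studies where a few nominal samples are missing.
    """
    obs_idx = table.index[table["EVID"] == 0]
    bad = [i for i in indices if i < 0 or i >= len(obs_idx)]
    if bad:
        raise IndexError(f"observation indices out of range: {bad}")
    return table.drop(index=obs_idx[list(indices)]).reset_index(drop=True)


def generate_calibration(
    levels: Sequence[float],
    n_reps: int,
    slope: float = 1000.0,
    intercept: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate calibration/repeatability table: signal vs nominal level.

    Each of the ``n_reps`` replicate sets measures every level once, with
    proportional noise of ``noise_cv`` on the ideal straight-line signal.
    """
    levels = np.asarray(levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("calibration levels must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_reps + 1):
        ideal = intercept + slope * levels
        noise = rng.normal(0.0, noise_cv, size=levels.shape) if noise_cv else 0.0
        signal = ideal * (1.0 + noise)
        for level, sig in zip(levels, signal):
            rows.append({"set": rep, "level_ppb": level, "signal": sig})
    return pd.DataFrame(rows)


def generate_tissue(
    median_by_tissue: Mapping[str, float],
    spread: float,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normal endpoint tissue concentrations around stated medians."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for tissue, median in median_by_tissue.items():
        if median <= 0:
            raise ValueError(f"median for {tissue!r} must be positive")
        values = median * np.exp(rng.normal(0.0, spread, size=n))
        for rep, value in enumerate(values, start=1):
            rows.append({"tissue": tissue, "replicate": rep, "conc_ug_g": value})
    return pd.DataFrame(rows)
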