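"""Closed-form two-compartment disposition model with IV-bolus and first-order
absorption (depot) inputs.

All concentrations come from the standard bi-/tri-exponential solutions of the
linear two-compartment system, parameterized by clearances and volumes:

* ``CL``  – elimination clearance from the central compartment (L/h)
* ``Vc``  – central volume (L)
* ``CLD`` – intercompartmental (distribution) clearance (L/h)
* ``VP``  – peripheral volume (L)
* ``Ka``  – first-order absorption rate constant for the depot route (1/h)
* ``F``   – absolute bioavailability of the depot route (fraction)

Units are fixed package-wide: time in hours, amounts in mg, volumes in L,
concentrations in mg/L (numerically identical to ug/mL), rate constants 1/h.

Because the system is linear, multiple-dose profiles are plain superpositions
of time-shifted single-dose solutions (:func:`superpose`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Route",
    "ThetaFixed",
    "MicroParams",
    "DoseEvent",
    "ProfileSet",
    "macro_to_micro",
    "conc_iv_bolus",
    "conc_first_order_abs",
    "superpose",
    "amount_remaining",
]

logger = logging.getLogger(__name__)

#: Relative closeness at which Ka is considered coincident with a disposition
#: rate constant; the coincident case is handled by a tiny perturbation of Ka
#: rather than by the t*exp(-k*t) limit form.
_COINCIDENT_RTOL = 1e-9
_COINCIDENT_NUDGE = 1e-6


class Route(str, Enum):
    """Administration route of a dose event."""

    IV_BOLUS = "iv"
    IM = "im"

    @classmethod
    def coerce(cls, value: "Route | str | int") -> "Route":
        """Accept Route, 'iv'/'im' strings or the CSV codes 1 (IV) / 2 (IM)."""
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            if int(value) == 1:
                return cls.IV_BOLUS
            if int(value) == 2:
                return cls.IM
            raise ValueError(f"unknown route code {value!r} (use 1=IV, 2=IM)")
        v = str(value).strip().lower()
        if v in ("iv", "iv_bolus", "bolus", "1"):
            return cls.IV_BOLUS
        if v in ("im", "depot", "2"):
            return cls.IM
        raise ValueError(f"unknown route {value!r}")


@dataclass(frozen=True)
class ThetaFixed:
    """Typical-value (fixed-effect) parameter vector of the structural model."""

    cl: float
    vc: float
    cld: float
    vp: float
    ka: float
    f: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "cld", "vp", "ka", "f"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0.0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.f > 1.0:
            raise ValueError(f"bioavailability f must be <= 1, got {self.f!r}")

    def as_dict(self) -> dict[str, float]:
        return {
            "cl": self.cl,
            "vc": self.vc,
            "cld": self.cld,
            "vp": self.vp,
            "ka": self.ka,
            "f": self.f,
        }

    def replace(self, **kwargs: float) -> "ThetaFixed":
        merged = {**self.as_dict(), **kwargs}
        return ThetaFixed(**merged)


@dataclass(frozen=True)
class MicroParams:
    """Micro-constant reparameterization of the two-compartment model.

    ``alpha``/``beta`` are the hybrid disposition rate constants (alpha >= beta)
    and ``a``/``b`` the macro intercepts of a *unit* IV bolus, so that a bolus
    of ``dose`` mg gives ``C(t) = dose * (a*exp(-alpha*t) + b*exp(-beta*t))``.
    """

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float
    a: float
    b: float


@dataclass(frozen=True)
class DoseEvent:
    """A single administration at ``time`` hours of ``amount`` mg."""

    time: float
    amount: float
    route: Route = Route.IV_BOLUS

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time!r}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount!r}")
        object.__setattr__(self, "route", Route.coerce(self.route))


@dataclass
class ProfileSet:
    """Concentration-time profiles on a common grid.

    ``conc`` is either 1-D ``(nt,)`` (single profile) or 2-D
    ``(n_profiles, nt)`` (e.g. a population band).
    """

    time_h: np.ndarray
    conc: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict)

    def to_frame(self, subject: str = "typical", route: str = ""):
        import pandas as pd

        conc = np.atleast_2d(self.conc)
        frames = []
        for i, row in enumerate(conc):
            name = subject if conc.shape[0] == 1 else f"{subject}_{i + 1}"
            frames.append(
                pd.DataFrame(
                    {
                        "subject": name,
                        "route": route or self.label,
                        "time_h": self.time_h,
                        "conc_ug_mL": row,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# vectorized kernels (used by the estimation and simulation machinery)
# ---------------------------------------------------------------------------

def disposition_terms(cl, vc, cld, vp):
    """Hybrid rate constants and unit-bolus intercepts; accepts arrays.

    Returns ``(alpha, beta, a, b, k10, k12, k21)`` broadcast over the inputs.
    ``beta`` is computed as ``k10*k21/alpha`` which is numerically stable when
    the two roots are far apart (the usual case for fast distribution).
    """
    cl = np.asarray(cl, dtype=float)
    vc = np.asarray(vc, dtype=float)
    cld = np.asarray(cld, dtype=float)
    vp = np.asarray(vp, dtype=float)
    # extreme parameter proposals from optimizers can overflow transiently;
    # the resulting non-finite likelihoods are guarded upstream
    with np.errstate(all="ignore"):
        k10 = cl / vc
        k12 = cld / vc
        k21 = cld / vp
        s = k10 + k12 + k21
        p = k10 * k21
        disc = s * s - 4.0 * p
        # disc = (k10+k12-k21)^2 + 2*k12*k21 + ... >= 0 for positive rates
        disc = np.maximum(disc, 0.0)
        alpha = 0.5 * (s + np.sqrt(disc))
        beta = np.where(alpha > 0, p / np.where(alpha > 0, alpha, 1.0), 0.0)
        denom = (alpha - beta) * vc
        a = (alpha - k21) / denom
        b = (k21 - beta) / denom
    return alpha, beta, a, b, k10, k12, k21


def iv_bolus_conc(cl, vc, cld, vp, dose, t):
    """Concentration after an IV bolus; fully vectorized over params and t."""
    alpha, beta, a, b, *_ = disposition_terms(cl, vc, cld, vp)
    t = np.asarray(t, dtype=float)
    with np.errstate(under="ignore"):
        return np.asarray(dose) * (a * np.exp(-alpha * t) + b * np.exp(-beta * t))


def _separate_ka(ka, alpha, beta):
    """Nudge Ka away from alpha/beta where coincident (logged, elementwise)."""
    ka = np.asarray(ka, dtype=float)
    with np.errstate(invalid="ignore"):
        close = (np.abs(ka - alpha) <= _COINCIDENT_RTOL * np.abs(alpha)) | (
            np.abs(ka - beta) <= _COINCIDENT_RTOL * np.abs(beta)
        )
    if np.any(close):
        logger.warning(
            "Ka coincides with a disposition rate constant; perturbing by %g "
            "relative to avoid the degenerate closed form",
            _COINCIDENT_NUDGE,
        )
        ka = np.where(close, ka * (1.0 + _COINCIDENT_NUDGE), ka)
    return ka


def first_order_abs_conc(cl, vc, cld, vp, ka, f, dose, t):
    """Concentration after an extravascular first-order-absorbed dose."""
    alpha, beta, a_iv, b_iv, k10, k12, k21 = disposition_terms(cl, vc, cld, vp)
    ka = _separate_ka(ka, alpha, beta)
    t = np.asarray(t, dtype=float)
    with np.errstate(all="ignore"):
        c_alpha = (k21 - alpha) / ((ka - alpha) * (beta - alpha))
        c_beta = (k21 - beta) / ((ka - beta) * (alpha - beta))
        c_ka = (k21 - ka) / ((alpha - ka) * (beta - ka))
        scale = np.asarray(f) * np.asarray(dose) * ka / vc
        out = scale * (
            c_alpha * np.exp(-alpha * t)
            + c_beta * np.exp(-beta * t)
            + c_ka * np.exp(-ka * t)
        )
    return out


# ---------------------------------------------------------------------------
# public scalar operations
# ---------------------------------------------------------------------------

def macro_to_micro(theta: ThetaFixed) -> MicroParams:
    """Convert clearance/volume parameters to micro/hybrid rate constants."""
    alpha, beta, a, b, k10, k12, k21 = disposition_terms(
        theta.cl, theta.vc, theta.cld, theta.vp
    )
    alpha = float(alpha)
    beta = float(beta)
    if not alpha >= beta:  # pragma: no cover - cannot happen for positive rates
        raise AssertionError("alpha < beta: invalid disposition roots")
    return MicroParams(
        k10=float(k10),
        k12=float(k12),
        k21=float(k21),
        alpha=alpha,
        beta=beta,
        a=float(a),
        b=float(b),
    )


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    return t


def conc_iv_bolus(theta: ThetaFixed, dose: float, t) -> np.ndarray:
    """Plasma concentration (ug/mL) after a single IV bolus at t=0."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    t = _check_times(t)
    return iv_bolus_conc(theta.cl, theta.vc, theta.cld, theta.vp, dose, t)


def conc_first_order_abs(theta: ThetaFixed, dose: float, t) -> np.ndarray:
    """Plasma concentration (ug/mL) after a single depot (IM) dose at t=0.

    The depot receives ``theta.f * dose`` and empties with rate ``theta.ka``;
    C(0) = 0 by construction.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    t = _check_times(t)
    return first_order_abs_conc(
        theta.cl, theta.vc, theta.cld, theta.vp, theta.ka, theta.f, dose, t
    )


def _single_dose_conc(theta: ThetaFixed, event: DoseEvent, t: np.ndarray) -> np.ndarray:
    dt = t - event.time
    out = np.zeros_like(np.asarray(dt, dtype=float))
    after = dt >= 0
    if not np.any(after):
        return out
    if event.route is Route.IV_BOLUS:
        out[after] = conc_iv_bolus(theta, event.amount, dt[after])
    else:
        out[after] = conc_first_order_abs(theta, event.amount, dt[after])
    return out


def superpose(
    events: Sequence[DoseEvent] | Iterable[DoseEvent],
    theta: ThetaFixed,
    t_grid,
) -> ProfileSet:
    """Total concentration of a multi-dose history by linear superposition."""
    events = list(events)
    t_grid = _check_times(t_grid)
    times = [ev.time for ev in events]
    if times != sorted(times):
        logger.warning("dose events were not time-sorted; reordering")
        events = sorted(events, key=lambda ev: ev.time)
    conc = np.zeros_like(t_grid, dtype=float)
    for ev in events:
        conc += _single_dose_conc(theta, ev, t_grid)
    return ProfileSet(time_h=t_grid, conc=conc)


def auc_zero_to(theta: ThetaFixed, dose: float, route: Route, t) -> np.ndarray:
    """Analytic AUC(0, t) of a single dose (ug*h/mL); t may be an array.

    At ``t -> inf`` this converges to ``dose/CL`` (IV) or ``F*dose/CL`` (IM).
    """
    route = Route.coerce(route)
    t = _check_times(t)
    m = macro_to_micro(theta)
    with np.errstate(under="ignore"):
        if route is Route.IV_BOLUS:
            return dose * (
                m.a / m.alpha * (1.0 - np.exp(-m.alpha * t))
                + m.b / m.beta * (1.0 - np.exp(-m.beta * t))
            )
        ka = float(_separate_ka(theta.ka, m.alpha, m.beta))
        c_alpha = (m.k21 - m.alpha) / ((ka - m.alpha) * (m.beta - m.alpha))
        c_beta = (m.k21 - m.beta) / ((ka - m.beta) * (m.alpha - m.beta))
        c_ka = (m.k21 - ka) / ((m.alpha - ka) * (m.beta - ka))
        scale = theta.f * dose * ka / theta.vc
        return scale * (
            c_alpha / m.alpha * (1.0 - np.exp(-m.alpha * t))
            + c_beta / m.beta * (1.0 - np.exp(-m.beta * t))
            + c_ka / ka * (1.0 - np.exp(-ka * t))
        )


def amount_remaining(theta: ThetaFixed, dose: float, route: Route, t) -> np.ndarray:
    """Total drug amount (mg) still in the body (incl. depot) at time t.

    Uses mass balance: amount remaining = systemically available dose minus
    the amount eliminated, ``CL * AUC(0, t)``.  For IV the available dose is
    ``dose``; for IM it is ``F * dose``.
    """
    route = Route.coerce(route)
    available = dose if route is Route.IV_BOLUS else theta.f * dose
    return available - theta.cl * auc_zero_to(theta, dose, route, t)
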