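"""Nonlinear mixed-effects estimation for the two-compartment IV+IM model.

Both administration routes are analyzed simultaneously.  Individual
parameters are modeled exponentially, ``p_i = p_typ * exp(eta_i)`` (logit
scale for bioavailability), with diagonal between-subject variance by
default; variances without support in the data are held fixed at 0.0225
(15% CV).  Residual error is proportional by default, with additive and
combined alternatives available for model comparison.

Two estimation back-ends share all the surrounding machinery:

* ``SAEM`` – stochastic approximation EM with a Metropolis-within-Gibbs
  E-step and closed-form M-steps (the linear/Gaussian latent structure makes
  the sufficient statistics exact).  Final objective function values are
  obtained by importance sampling around the empirical Bayes modes.
* ``LAPLACE`` – deterministic marginal-likelihood maximization where each
  subject's random effects are profiled out with a Gauss-Newton inner
  optimizer and a Laplace correction.

Standard errors come from a finite-difference observed information matrix of
the Laplace marginal likelihood; the condition number is the eigenvalue
ratio of the fixed-effect correlation matrix.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from scipy.special import expit, logit

from .model import ThetaFixed, first_order_abs_conc, iv_bolus_conc

__all__ = [
    "PARAM_NAMES",
    "PopulationModel",
    "FitResult",
    "StackedData",
    "stack_events",
    "subject_loglik",
    "fit_population",
    "compare_models",
    "ModelComparison",
    "apply_allometry",
    "shrinkage",
    "condition_number",
    "residual_diagnostics",
    "initial_from_nca",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("cl", "vc", "cld", "vp", "ka", "f")
_F_INDEX = 5
_FLOW_IDX = (0, 2)  # cl, cld
_VOL_IDX = (1, 3)  # vc, vp
_LOG2PI = math.log(2.0 * math.pi)
_F_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# model / data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationModel:
    """Population model specification and initial estimates.

    ``omega_sd`` lists the parameters whose between-subject SD is *estimated*
    (with initial values); every other parameter keeps ``fixed_omega_sd``
    throughout the fit.  ``covariate_model`` is one of ``none``,
    ``allometric_fixed`` (0.75 on flows, 1.0 on volumes, referenced to
    ``ref_bw``) or ``allometric_estimated`` (the two exponents estimated).
    """

    theta: ThetaFixed
    omega_sd: Mapping[str, float] = field(
        default_factory=lambda: {"cl": 0.3, "vc": 0.3, "ka": 0.5}
    )
    fixed_omega_sd: float = 0.15
    sigma_prop: float = 0.3
    sigma_add: float = 0.0
    residual_error: str = "proportional"  # proportional | additive | combined
    covariate_model: str = "none"
    ref_bw: float = 70.0
    exponents: tuple[float, float] = (0.75, 1.0)  # (flows, volumes)
    omega_block: bool = False

    def __post_init__(self) -> None:
        for key, value in self.omega_sd.items():
            if key not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {key!r} in omega_sd")
            if not value > 0:
                raise ValueError("estimated omega_sd initials must be > 0")
        if self.residual_error not in ("proportional", "additive", "combined"):
            raise ValueError(f"unknown residual_error {self.residual_error!r}")
        if self.covariate_model not in (
            "none", "allometric_fixed", "allometric_estimated",
        ):
            raise ValueError(f"unknown covariate_model {self.covariate_model!r}")
        if self.residual_error != "additive" and not self.sigma_prop > 0:
            raise ValueError("sigma_prop initial must be > 0")
        if self.residual_error != "proportional" and not self.sigma_add > 0:
            raise ValueError("sigma_add initial must be > 0")

    @property
    def estimated_omega(self) -> tuple[str, ...]:
        return tuple(self.omega_sd.keys())

    def omega_vector(self) -> np.ndarray:
        return np.array(
            [
                float(self.omega_sd.get(name, self.fixed_omega_sd))
                for name in PARAM_NAMES
            ]
        )


@dataclass
class StackedData:
    """Event table rearranged into padded per-subject observation matrices."""

    ids: np.ndarray
    y: np.ndarray
    t: np.ndarray
    is_iv: np.ndarray
    mask: np.ndarray
    dose_iv: np.ndarray
    dose_im: np.ndarray
    bw: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    @property
    def routes_present(self) -> set[str]:
        out = set()
        if np.any(self.mask & self.is_iv):
            out.add("iv")
        if np.any(self.mask & ~self.is_iv):
            out.add("im")
        return out

    def hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.ids, self.y, self.t, self.is_iv, self.mask,
                    self.dose_iv, self.dose_im, self.bw):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]

    def subset(self, indices: Sequence[int]) -> "StackedData":
        idx = np.asarray(indices, dtype=int)
        return StackedData(
            ids=np.arange(1, len(idx) + 1),
            y=self.y[idx], t=self.t[idx], is_iv=self.is_iv[idx],
            mask=self.mask[idx], dose_iv=self.dose_iv[idx],
            dose_im=self.dose_im[idx], bw=self.bw[idx],
        )


def stack_events(events: pd.DataFrame) -> StackedData:
    """Build a :class:`StackedData` from the long event-table format."""
    ids, ys, ts, ivs, doses_iv, doses_im, bws = [], [], [], [], [], [], []
    for subject, group in events.groupby("ID", sort=True):
        obs = group[group["EVID"] == 0].sort_values(["ROUTE", "TIME"])
        dose = group[group["EVID"] == 1]
        d_iv = float(dose.loc[dose["ROUTE"] == 1, "AMT"].sum())
        d_im = float(dose.loc[dose["ROUTE"] == 2, "AMT"].sum())
        route = obs["ROUTE"].to_numpy()
        if np.any((route == 1)) and d_iv == 0.0:
            raise ValueError(f"subject {subject}: IV observations without an IV dose")
        if np.any((route == 2)) and d_im == 0.0:
            raise ValueError(f"subject {subject}: IM observations without an IM dose")
        ids.append(subject)
        ys.append(obs["DV"].to_numpy(dtype=float))
        ts.append(obs["TIME"].to_numpy(dtype=float))
        ivs.append(route == 1)
        doses_iv.append(d_iv)
        doses_im.append(d_im)
        bws.append(float(group["BW"].iloc[0]) if "BW" in group else np.nan)
    n = len(ids)
    if n == 0:
        raise ValueError("no subjects with observations in the event table")
    m = max(len(y) for y in ys)
    y = np.ones((n, m))
    t = np.zeros((n, m))
    is_iv = np.ones((n, m), dtype=bool)
    mask = np.zeros((n, m), dtype=bool)
    for i in range(n):
        k = len(ys[i])
        y[i, :k] = ys[i]
        t[i, :k] = ts[i]
        is_iv[i, :k] = ivs[i]
        mask[i, :k] = True
    return StackedData(
        ids=np.asarray(ids), y=y, t=t, is_iv=is_iv, mask=mask,
        dose_iv=np.asarray(doses_iv), dose_im=np.asarray(doses_im),
        bw=np.asarray(bws),
    )


# ---------------------------------------------------------------------------
# transforms and prediction
# ---------------------------------------------------------------------------

def transform_theta(theta: ThetaFixed) -> np.ndarray:
    """Typical values -> unconstrained scale (log; logit for F)."""
    vals = theta.as_dict()
    out = [math.log(vals[name]) for name in PARAM_NAMES[:_F_INDEX]]
    f = min(max(vals["f"], 1e-10), 1.0 - 1e-10)
    out.append(float(logit(f)))
    return np.asarray(out)


def untransform_mu(mu: np.ndarray) -> ThetaFixed:
    vals = {name: float(np.exp(mu[j])) for j, name in enumerate(PARAM_NAMES[:_F_INDEX])}
    vals["f"] = float(expit(mu[_F_INDEX]))
    return ThetaFixed(**vals)


def _predict(phi: np.ndarray, data: StackedData, tlag: float = 0.0) -> np.ndarray:
    """Predicted concentrations (n, m) for transformed parameters (n, 6)."""
    with np.errstate(over="ignore"):
        cl = np.exp(phi[:, 0])[:, None]
        vc = np.exp(phi[:, 1])[:, None]
        cld = np.exp(phi[:, 2])[:, None]
        vp = np.exp(phi[:, 3])[:, None]
        ka = np.exp(phi[:, 4])[:, None]
        f = expit(phi[:, 5])[:, None]
    c_iv = iv_bolus_conc(cl, vc, cld, vp, data.dose_iv[:, None], data.t)
    t_im = np.maximum(data.t - tlag, 0.0)
    c_im = first_order_abs_conc(
        cl, vc, cld, vp, ka, f, data.dose_im[:, None], t_im
    )
    return np.where(data.is_iv, c_iv, c_im)


def _residual_sd(f: np.ndarray, sig_prop: float, sig_add: float, kind: str):
    f_safe = np.maximum(f, _F_FLOOR)
    if kind == "proportional":
        return sig_prop * f_safe
    if kind == "additive":
        return np.full_like(f_safe, sig_add)
    return np.sqrt(sig_add**2 + (sig_prop * f_safe) ** 2)


def _obs_loglik(
    y: np.ndarray, f: np.ndarray, mask: np.ndarray,
    sig_prop: float, sig_add: float, kind: str,
) -> np.ndarray:
    """Per-subject observation log-likelihood; f <= 0 floored with a flag."""
    if np.any(mask & (f <= 0)):
        logger.debug("non-positive prediction floored at %g", _F_FLOOR)
    f_safe = np.maximum(f, _F_FLOOR)
    sd = _residual_sd(f_safe, sig_prop, sig_add, kind)
    ll = -0.5 * ((y - f_safe) / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI
    return np.where(mask, ll, 0.0).sum(axis=-1)


def subject_loglik(
    y,
    t,
    is_iv,
    dose_iv: float,
    dose_im: float,
    theta: ThetaFixed,
    eta,
    sigma_prop: float,
) -> float:
    """Observation log-density of one subject given its random effects.

    ``eta`` is the 6-vector of unconstrained-scale deviations; the subject's
    parameters are ``typical * exp(eta)`` (logit-shifted for F), shared by
    both occasions.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    t = np.atleast_1d(np.asarray(t, dtype=float))
    is_iv = np.atleast_1d(np.asarray(is_iv, dtype=bool))
    data = StackedData(
        ids=np.array([1]), y=y[None, :], t=t[None, :], is_iv=is_iv[None, :],
        mask=np.ones((1, len(y)), dtype=bool),
        dose_iv=np.array([dose_iv]), dose_im=np.array([dose_im]),
        bw=np.array([np.nan]),
    )
    phi = (transform_theta(theta) + np.asarray(eta, dtype=float))[None, :]
    f = _predict(phi, data)
    return float(_obs_loglik(data.y, f, data.mask, sigma_prop, 0.0, "proportional")[0])


# ---------------------------------------------------------------------------
# fit result
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimates plus the usual fit metadata."""

    method: str
    status: str
    theta: ThetaFixed
    omega_sd: dict[str, float]
    omega_fixed: dict[str, bool]
    sigma_prop: float
    sigma_add: float
    residual_error: str
    covariate_model: str
    ref_bw: float
    exponents: tuple[float, float]
    mofv: float
    aic: float
    n_params: int
    mu: np.ndarray
    ebe: pd.DataFrame
    data_hash: str
    n_subjects: int
    n_obs: int
    seed: int
    rse_pct: Optional[dict[str, float]] = None
    covariance: Optional[np.ndarray] = None
    param_order: Optional[list[str]] = None
    eta_shrinkage_pct: dict[str, float] = field(default_factory=dict)
    eps_shrinkage_pct: float = np.nan
    condition_number: float = np.nan
    trace: Optional[pd.DataFrame] = None
    tlag: float = 0.0

    @property
    def iiv_cv_pct(self) -> dict[str, float]:
        """Between-subject variability reported as CV% (100 * SD)."""
        return {k: 100.0 * v for k, v in self.omega_sd.items()}

    @property
    def sigma_cv_pct(self) -> float:
        return 100.0 * self.sigma_prop

    def estimates_table(self) -> pd.DataFrame:
        """Tidy parameter table (typical values, IIV CV%, residual CV%)."""
        rows = []
        vals = self.theta.as_dict()
        for name in PARAM_NAMES:
            value = vals[name] * 100.0 if name == "f" else vals[name]
            rows.append({
                "parameter": name, "kind": "typical", "estimate": value,
                "rse_pct": (self.rse_pct or {}).get(name, np.nan),
            })
        for name in PARAM_NAMES:
            if not self.omega_fixed[name]:
                rows.append({
                    "parameter": f"iiv_{name}", "kind": "iiv_cv_pct",
                    "estimate": 100.0 * self.omega_sd[name],
                    "rse_pct": (self.rse_pct or {}).get(f"omega_{name}", np.nan),
                })
        if self.residual_error in ("proportional", "combined"):
            rows.append({
                "parameter": "sigma_prop", "kind": "residual_cv_pct",
                "estimate": 100.0 * self.sigma_prop,
                "rse_pct": (self.rse_pct or {}).get("sigma_prop", np.nan),
            })
        if self.residual_error in ("additive", "combined"):
            rows.append({
                "parameter": "sigma_add", "kind": "residual_sd",
                "estimate": self.sigma_add,
                "rse_pct": (self.rse_pct or {}).get("sigma_add", np.nan),
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "status": self.status,
            "theta": self.theta.as_dict(),
            "omega_sd": self.omega_sd,
            "omega_fixed": self.omega_fixed,
            "sigma_prop": self.sigma_prop,
            "sigma_add": self.sigma_add,
            "residual_error": self.residual_error,
            "covariate_model": self.covariate_model,
            "ref_bw": self.ref_bw,
            "exponents": list(self.exponents),
            "mofv": self.mofv,
            "aic": self.aic,
            "n_params": self.n_params,
            "rse_pct": self.rse_pct,
            "eta_shrinkage_pct": self.eta_shrinkage_pct,
            "eps_shrinkage_pct": self.eps_shrinkage_pct,
            "condition_number": self.condition_number,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "seed": self.seed,
            "data_hash": self.data_hash,
            "tlag": self.tlag,
            "mu": [float(v) for v in self.mu],
            "ebe": self.ebe.to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FitResult":
        payload = dict(payload)
        payload["theta"] = ThetaFixed(**payload["theta"])
        payload["mu"] = np.asarray(payload["mu"], dtype=float)
        payload["ebe"] = pd.DataFrame(payload["ebe"])
        payload["exponents"] = tuple(payload["exponents"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# covariate handling
# ---------------------------------------------------------------------------

def _covariate_x(data: StackedData, model: PopulationModel) -> np.ndarray:
    if model.covariate_model == "none":
        return np.zeros(data.n_subjects)
    if np.any(~np.isfinite(data.bw)) or np.any(data.bw <= 0):
        raise ValueError("bodyweight required (and positive) for allometric models")
    return np.log(data.bw / model.ref_bw)


def _mu_matrix(
    mu: np.ndarray, x: np.ndarray, exponents: tuple[float, float],
    covariate_model: str,
) -> np.ndarray:
    """Per-subject unconstrained-scale typical values (n, 6)."""
    n = len(x)
    mu_i = np.broadcast_to(mu, (n, len(mu))).copy()
    if covariate_model != "none":
        b_flow, b_vol = exponents
        for j in _FLOW_IDX:
            mu_i[:, j] += b_flow * x
        for j in _VOL_IDX:
            mu_i[:, j] += b_vol * x
    return mu_i


def apply_allometry(
    theta: ThetaFixed,
    bw: float,
    exponents: tuple[float, float] = (0.75, 1.0),
    ref_bw: float = 70.0,
) -> ThetaFixed:
    """Scale flow parameters by (bw/ref)^b_flow and volumes by (bw/ref)^b_vol.

    Ka and F are left untouched.
    """
    if not bw > 0:
        raise ValueError("bw must be > 0")
    ratio = bw / ref_bw
    b_flow, b_vol = exponents
    return theta.replace(
        cl=theta.cl * ratio**b_flow,
        cld=theta.cld * ratio**b_flow,
        vc=theta.vc * ratio**b_vol,
        vp=theta.vp * ratio**b_vol,
    )


# ---------------------------------------------------------------------------
# inner problem: empirical Bayes modes by Gauss-Newton
# ---------------------------------------------------------------------------

def _neg_logpost(
    phi: np.ndarray, mu_i: np.ndarray, prec_diag: np.ndarray,
    data: StackedData, sig_prop: float, sig_add: float, kind: str,
    tlag: float, prec_full: Optional[np.ndarray] = None,
) -> np.ndarray:
    f = _predict(phi, data, tlag)
    ll = _obs_loglik(data.y, f, data.mask, sig_prop, sig_add, kind)
    d = phi - mu_i
    if prec_full is not None:
        lp = -0.5 * np.einsum("ni,ij,nj->n", d, prec_full, d)
    else:
        lp = -0.5 * np.sum(d * d * prec_diag, axis=1)
    return -(ll + lp)


def _dll_df_and_weight(y, f, mask, sig_prop, sig_add, kind):
    """Gradient of the observation log-lik w.r.t. the prediction, plus the
    Fisher weight used as the Gauss-Newton metric (mean and variance both
    depend on f)."""
    f_safe = np.maximum(f, _F_FLOOR)
    r = y - f_safe
    if kind == "additive":
        v = np.full_like(f_safe, sig_add**2)
        dv = np.zeros_like(f_safe)
    elif kind == "proportional":
        v = (sig_prop * f_safe) ** 2
        dv = 2.0 * sig_prop**2 * f_safe
    else:
        v = sig_add**2 + (sig_prop * f_safe) ** 2
        dv = 2.0 * sig_prop**2 * f_safe
    g = r / v + 0.5 * r * r * dv / (v * v) - 0.5 * dv / v
    w = 1.0 / v + 0.5 * (dv / v) ** 2
    return np.where(mask, g, 0.0), np.where(mask, w, 0.0)


def _map_phi(
    mu_i: np.ndarray, omega: np.ndarray, data: StackedData,
    sig_prop: float, sig_add: float, kind: str,
    phi0: Optional[np.ndarray] = None, tlag: float = 0.0,
    prec_full: Optional[np.ndarray] = None,
    n_iter: int = 40, tol: float = 1e-6, gain_tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-subject MAP of phi via damped Gauss-Newton (vectorized over
    subjects).  Coordinates with omega == 0 stay pinned at mu.

    Returns ``(phi_hat, hessian, neg_logpost, active_mask)`` where ``hessian``
    is the (n, d, d) Gauss-Newton curvature over the active coordinates.
    """
    n, k = mu_i.shape
    active = omega > 0
    d = int(active.sum())
    prec_diag = np.where(active, 1.0 / np.where(active, omega, 1.0) ** 2, 0.0)
    phi = mu_i.copy() if phi0 is None else phi0.copy()
    phi[:, ~active] = mu_i[:, ~active]

    def objective(p):
        return _neg_logpost(p, mu_i, prec_diag, data, sig_prop, sig_add, kind,
                            tlag, prec_full)

    obj = objective(phi)
    h_step = 1e-5
    hessian = np.tile(np.eye(d), (n, 1, 1))
    act_idx = np.flatnonzero(active)
    if prec_full is not None:
        prec_act = prec_full[np.ix_(act_idx, act_idx)]
    else:
        prec_act = np.diag(prec_diag[act_idx])
    for _ in range(n_iter):
        f = _predict(phi, data, tlag)
        jac = np.empty((n, f.shape[1], d))
        for jj, j in enumerate(act_idx):
            phi_p = phi.copy()
            phi_p[:, j] += h_step
            jac[:, :, jj] = (_predict(phi_p, data, tlag) - f) / h_step
        g_f, w = _dll_df_and_weight(data.y, f, data.mask, sig_prop, sig_add, kind)
        dphi = phi - mu_i
        if prec_full is not None:
            grad_prior = dphi[:, act_idx] @ prec_act
        else:
            grad_prior = dphi[:, act_idx] * prec_diag[act_idx]
        grad = -np.einsum("nmj,nm->nj", jac, g_f) + grad_prior
        hessian = np.einsum("nmi,nm,nmj->nij", jac, w, jac) + prec_act[None, :, :]
        try:
            step = -np.linalg.solve(hessian, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:  # pragma: no cover - guarded metric
            hessian = hessian + 1e-8 * np.eye(d)[None]
            step = -np.linalg.solve(hessian, grad[:, :, None])[:, :, 0]
        if not np.all(np.isfinite(step)):
            step = np.where(np.isfinite(step), step, 0.0)
        # subjects already at their mode take no step (and no line search)
        done = np.max(np.abs(step), axis=1) < tol
        step[done] = 0.0
        if np.all(done):
            break
        # per-subject backtracking line search
        alpha = np.ones(n)
        improved = done.copy()
        phi_new = phi.copy()
        obj_new = obj.copy()
        for _ls in range(20):
            todo = ~improved
            if not np.any(todo):
                break
            cand = phi.copy()
            cand[:, act_idx] = phi[:, act_idx] + alpha[:, None] * step
            obj_cand = objective(cand)
            better = todo & (obj_cand <= obj + 1e-8 * np.abs(obj) + 1e-10)
            phi_new[better] = cand[better]
            obj_new[better] = obj_cand[better]
            improved |= better
            alpha[todo & ~better] *= 0.5
            if np.all(alpha[~improved] < 1e-6) if np.any(~improved) else True:
                break
        max_move = np.max(np.abs(phi_new - phi)) if n else 0.0
        gain = float(np.sum(obj - obj_new))
        phi, obj = phi_new, obj_new
        # flat-valley crawling (ill-identified coordinates) yields sub-1e-3
        # gains that are irrelevant at the outer optimizer's tolerance
        if max_move < tol or gain < gain_tol:
            break
    return phi, hessian, obj, active


def _laplace_m2ll(
    mu_i, omega, data, sig_prop, sig_add, kind, phi0=None, tlag=0.0,
    prec_full=None, tight: bool = False,
) -> tuple[float, np.ndarray]:
    """-2 * marginal log-likelihood by the Laplace approximation.

    ``tight`` runs the inner solver to near machine tolerance (needed when
    the result feeds finite differences, e.g. the information matrix).
    """
    inner = {"n_iter": 120, "tol": 1e-9, "gain_tol": 1e-8} if tight else {}
    phi, hess, neg_post, active = _map_phi(
        mu_i, omega, data, sig_prop, sig_add, kind, phi0=phi0, tlag=tlag,
        prec_full=prec_full, **inner,
    )
    d = int(active.sum())
    sign, logdet = np.linalg.slogdet(hess)
    if np.any(sign <= 0):  # pragma: no cover - GN metric is PSD by build
        logdet = np.where(sign > 0, logdet, np.inf)
    act_idx = np.flatnonzero(active)
    if prec_full is not None:
        prec_act = prec_full[np.ix_(act_idx, act_idx)]
        s, ld_prec = np.linalg.slogdet(prec_act)
        log_prior_norm = 0.5 * ld_prec - 0.5 * d * _LOG2PI
    else:
        log_prior_norm = (
            -np.sum(np.log(omega[act_idx])) - 0.5 * d * _LOG2PI
        )
    # neg_post already contains the unnormalized prior; add its normalizer
    log_l = -neg_post + log_prior_norm + 0.5 * d * _LOG2PI - 0.5 * logdet
    return float(-2.0 * np.sum(log_l)), phi


# ---------------------------------------------------------------------------
# importance-sampling objective function
# ---------------------------------------------------------------------------

def _importance_m2ll(
    mu_i, omega, data, sig_prop, sig_add, kind, phi_hat, hess, active,
    seed: int, n_is: int = 1000, tlag: float = 0.0,
    prec_full=None, chunk: int = 250,
) -> float:
    """-2 log-likelihood by importance sampling around the EBE modes.

    The proposal is the Gaussian Laplace approximation at each subject's mode;
    1000 seeded samples per subject give sub-unit Monte-Carlo jitter.
    """
    rng = np.random.default_rng(seed)
    n, k = mu_i.shape
    act_idx = np.flatnonzero(active)
    d = len(act_idx)
    if d == 0:
        f = _predict(mu_i, data, tlag)
        ll = _obs_loglik(data.y, f, data.mask, sig_prop, sig_add, kind)
        return float(-2.0 * ll.sum())
    cov = np.linalg.inv(hess)
    chol = np.linalg.cholesky(
        cov + 1e-12 * np.eye(d)[None]
    )  # (n, d, d)
    prec_diag = np.where(omega > 0, 1.0 / np.where(omega > 0, omega, 1.0) ** 2, 0.0)
    log_w_chunks = []
    sign, logdet_cov = np.linalg.slogdet(cov)
    for start in range(0, n_is, chunk):
        s = min(chunk, n_is - start)
        z = rng.standard_normal((n, s, d))
        delta = np.einsum("nij,nsj->nsi", chol, z)
        phi_s = np.repeat(phi_hat[:, None, :], s, axis=1)
        phi_s[:, :, act_idx] += delta
        flat = phi_s.reshape(n * s, k)
        rep = np.repeat(np.arange(n), s)
        data_rep = StackedData(
            ids=rep, y=data.y[rep], t=data.t[rep], is_iv=data.is_iv[rep],
            mask=data.mask[rep], dose_iv=data.dose_iv[rep],
            dose_im=data.dose_im[rep], bw=data.bw[rep],
        )
        f = _predict(flat, data_rep, tlag)
        ll = _obs_loglik(
            data_rep.y, f, data_rep.mask, sig_prop, sig_add, kind
        ).reshape(n, s)
        dphi = phi_s - mu_i[:, None, :]
        if prec_full is not None:
            lp = -0.5 * np.einsum("nsi,ij,nsj->ns", dphi, prec_full, dphi)
            _, ld_prec = np.linalg.slogdet(prec_full[np.ix_(act_idx, act_idx)])
            lp += 0.5 * ld_prec - 0.5 * d * _LOG2PI
        else:
            lp = -0.5 * np.sum(dphi * dphi * prec_diag, axis=2)
            lp += -np.sum(np.log(omega[act_idx])) - 0.5 * d * _LOG2PI
        log_q = (
            -0.5 * np.sum(z * z, axis=2)
            - 0.5 * d * _LOG2PI
            - 0.5 * logdet_cov[:, None]
        )
        log_w_chunks.append(ll + lp - log_q)
    log_w = np.concatenate(log_w_chunks, axis=1)
    m = log_w.max(axis=1)
    log_l = m + np.log(np.mean(np.exp(log_w - m[:, None]), axis=1))
    return float(-2.0 * log_l.sum())


# ---------------------------------------------------------------------------
# SAEM
# ---------------------------------------------------------------------------

def _fit_saem(
    data: StackedData,
    model: PopulationModel,
    seed: int,
    n_burn: int,
    n_smooth: int,
    n_kernel: int = 3,
    estimate_f: bool = True,
):
    rng = np.random.default_rng(seed)
    n = data.n_subjects
    k = len(PARAM_NAMES)
    mu = transform_theta(model.theta)
    omega = model.omega_vector()
    est_omega = np.array([name in model.omega_sd for name in PARAM_NAMES])
    sig_prop, sig_add = model.sigma_prop, model.sigma_add
    kind = model.residual_error
    x = _covariate_x(data, model)
    exponents = list(model.exponents)
    estimate_exp = model.covariate_model == "allometric_estimated"
    x_bar, x2_bar = float(x.mean()), float(np.mean(x * x))
    block_idx = np.flatnonzero(est_omega) if model.omega_block else None

    mu_i = _mu_matrix(mu, x, tuple(exponents), model.covariate_model)
    phi = mu_i + 0.1 * rng.standard_normal((n, k)) * np.where(omega > 0, omega, 0.0)
    prop_scale = np.where(omega > 0, omega, 0.0) * 0.8 + 0.05
    prec_full = None
    omega_blk = np.diag(omega[block_idx] ** 2) if block_idx is not None else None

    def prior_prec():
        nonlocal prec_full
        if block_idx is None:
            prec_full = None
            return np.where(omega > 0, 1.0 / np.where(omega > 0, omega, 1.0) ** 2, 0.0)
        prec = np.zeros((k, k))
        for j in range(k):
            if omega[j] > 0 and j not in block_idx:
                prec[j, j] = 1.0 / omega[j] ** 2
        inv_blk = np.linalg.inv(omega_blk)
        prec[np.ix_(block_idx, block_idx)] = inv_blk
        prec_full = prec
        return None

    prec_diag = prior_prec()

    def logpost(p):
        return -_neg_logpost(p, mu_i, prec_diag, data, sig_prop, sig_add,
                             kind, 0.0, prec_full)

    lp_cur = logpost(phi)
    s1 = np.zeros(k)
    s2 = np.zeros(k)
    sx = np.zeros(k)
    s_blk = np.zeros((len(block_idx), len(block_idx))) if block_idx is not None else None
    s_eps_prop = 0.0
    s_eps_add = 0.0
    n_obs = data.n_obs
    trace_rows = []
    total = n_burn + n_smooth
    free = omega > 0

    for it in range(total):
        gamma = 1.0 if it < n_burn else 1.0 / (it - n_burn + 1) ** 0.7
        for _ in range(n_kernel):
            for j in range(k):
                if not free[j] or (j == _F_INDEX and not estimate_f):
                    continue
                cand = phi.copy()
                cand[:, j] += prop_scale[j] * rng.standard_normal(n)
                lp_new = logpost(cand)
                accept = np.log(rng.uniform(size=n)) < (lp_new - lp_cur)
                phi[accept] = cand[accept]
                lp_cur = np.where(accept, lp_new, lp_cur)
                if it < n_burn:
                    rate = accept.mean()
                    prop_scale[j] *= math.exp(0.2 * (rate - 0.35))
        # sufficient statistics (stochastic approximation)
        f_pred = _predict(phi, data)
        f_safe = np.maximum(f_pred, _F_FLOOR)
        resid = np.where(data.mask, data.y - f_safe, 0.0)
        s1 += gamma * (phi.sum(axis=0) - s1)
        s2 += gamma * ((phi**2).sum(axis=0) - s2)
        sx += gamma * ((x[:, None] * phi).sum(axis=0) - sx)
        if block_idx is not None:
            d_blk = phi[:, block_idx] - mu_i[:, block_idx]
            s_blk += gamma * (d_blk.T @ d_blk - s_blk)
        s_eps_prop += gamma * (
            float(np.sum(np.where(data.mask, (resid / f_safe) ** 2, 0.0))) - s_eps_prop
        )
        s_eps_add += gamma * (float(np.sum(resid**2)) - s_eps_add)

        # M-step: typical values (and allometric exponents) by weighted LS
        if model.covariate_model == "none":
            mu_new = s1 / n
        else:
            mu_new = mu.copy()
            if estimate_exp:
                for group, gi in (("flow", _FLOW_IDX), ("vol", _VOL_IDX)):
                    denom = x2_bar - x_bar**2
                    if denom <= 0:
                        continue
                    w = 1.0 / omega[list(gi)] ** 2
                    num = sum(
                        w[a] * (sx[j] / n - x_bar * s1[j] / n)
                        for a, j in enumerate(gi)
                    )
                    beta = num / (w.sum() * denom)
                    if group == "flow":
                        exponents[0] = float(beta)
                    else:
                        exponents[1] = float(beta)
            b_flow, b_vol = exponents
            for j in range(k):
                b = b_flow if j in _FLOW_IDX else (b_vol if j in _VOL_IDX else 0.0)
                mu_new[j] = s1[j] / n - b * x_bar
        if not estimate_f:
            mu_new[_F_INDEX] = mu[_F_INDEX]
        mu = mu_new
        mu_i = _mu_matrix(mu, x, tuple(exponents), model.covariate_model)
        # omegas
        b_of = lambda j: (
            exponents[0] if (model.covariate_model != "none" and j in _FLOW_IDX)
            else exponents[1] if (model.covariate_model != "none" and j in _VOL_IDX)
            else 0.0
        )
        for j in range(k):
            if est_omega[j] and (block_idx is None or j not in block_idx):
                b = b_of(j)
                var = (
                    s2[j] / n
                    - 2.0 * mu[j] * s1[j] / n
                    - 2.0 * b * sx[j] / n
                    + mu[j] ** 2
                    + 2.0 * mu[j] * b * x_bar
                    + b * b * x2_bar
                )
                omega[j] = math.sqrt(max(var, 1e-8))
        if block_idx is not None:
            omega_blk = s_blk / n + 1e-10 * np.eye(len(block_idx))
            omega[block_idx] = np.sqrt(np.diag(omega_blk))
        # residual error
        if kind == "proportional":
            sig_prop = math.sqrt(max(s_eps_prop / n_obs, 1e-12))
        elif kind == "additive":
            sig_add = math.sqrt(max(s_eps_add / n_obs, 1e-12))
        else:
            sig_prop, sig_add = _combined_mstep(
                data, phi, sig_prop, sig_add
            )
        prec_diag = prior_prec()
        lp_cur = logpost(phi)
        trace_rows.append(
            {"iteration": it, "gamma": gamma, **{
                f"mu_{name}": mu[j] for j, name in enumerate(PARAM_NAMES)
            }, **{
                f"omega_{name}": omega[j] for j, name in enumerate(PARAM_NAMES)
            }, "sigma_prop": sig_prop, "sigma_add": sig_add}
        )
    trace = pd.DataFrame(trace_rows)
    return mu, omega, sig_prop, sig_add, tuple(exponents), trace, phi


def _combined_mstep(data, phi, sig_prop, sig_add):
    """Numeric M-step for the combined error model at the current phi."""
    f = np.maximum(_predict(phi, data), _F_FLOOR)
    r2 = np.where(data.mask, (data.y - f) ** 2, 0.0)
    f2 = f * f

    def nll(p):
        a2, b2 = np.exp(p)
        v = a2 + b2 * f2
        return float(np.sum(np.where(data.mask, r2 / v + np.log(v), 0.0)))

    res = optimize.minimize(
        nll, np.log([max(sig_add**2, 1e-8), max(sig_prop**2, 1e-8)]),
        method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
    )
    a2, b2 = np.exp(res.x)
    return math.sqrt(b2), math.sqrt(a2)


# ---------------------------------------------------------------------------
# LAPLACE outer optimization
# ---------------------------------------------------------------------------

class _ParamPacker:
    """Maps the free population parameters to an unconstrained vector."""

    def __init__(self, model: PopulationModel, estimate_f: bool,
                 estimate_tlag: bool = False):
        self.model = model
        self.estimate_f = estimate_f
        self.estimate_tlag = estimate_tlag
        self.names: list[str] = []
        for name in PARAM_NAMES:
            if name == "f" and not estimate_f:
                continue
            self.names.append(name)
        self.omega_names = [name for name in PARAM_NAMES if name in model.omega_sd]
        self.residual_names = []
        if model.residual_error in ("proportional", "combined"):
            self.residual_names.append("sigma_prop")
        if model.residual_error in ("additive", "combined"):
            self.residual_names.append("sigma_add")
        self.estimate_exp = model.covariate_model == "allometric_estimated"

    @property
    def full_names(self) -> list[str]:
        out = list(self.names)
        out += [f"omega_{n}" for n in self.omega_names]
        out += self.residual_names
        if self.estimate_exp:
            out += ["exp_flow", "exp_vol"]
        if self.estimate_tlag:
            out += ["tlag"]
        return out

    def pack(self, mu, omega, sig_prop, sig_add, exponents, tlag=0.0):
        parts = [mu[PARAM_NAMES.index(n)] for n in self.names]
        parts += [math.log(omega[PARAM_NAMES.index(n)]) for n in self.omega_names]
        for rn in self.residual_names:
            parts.append(math.log(sig_prop if rn == "sigma_prop" else sig_add))
        if self.estimate_exp:
            parts += list(exponents)
        if self.estimate_tlag:
            parts.append(math.log(max(tlag, 1e-4)))
        return np.asarray(parts, dtype=float)

    def unpack(self, p):
        mu = transform_theta(self.model.theta).copy()
        i = 0
        for n in self.names:
            mu[PARAM_NAMES.index(n)] = p[i]
            i += 1
        omega = self.model.omega_vector()
        for n in self.omega_names:
            omega[PARAM_NAMES.index(n)] = math.exp(p[i])
            i += 1
        sig_prop, sig_add = self.model.sigma_prop, self.model.sigma_add
        for rn in self.residual_names:
            if rn == "sigma_prop":
                sig_prop = math.exp(p[i])
            else:
                sig_add = math.exp(p[i])
            i += 1
        exponents = tuple(self.model.exponents)
        if self.estimate_exp:
            exponents = (p[i], p[i + 1])
            i += 2
        tlag = 0.0
        if self.estimate_tlag:
            tlag = math.exp(p[i])
            i += 1
        return mu, omega, sig_prop, sig_add, exponents, tlag

    @property
    def n_params(self) -> int:
        return len(self.full_names)


def _fit_laplace(
    data: StackedData, model: PopulationModel, estimate_f: bool,
    max_iter: int, estimate_tlag: bool = False, nm_restart: bool = True,
):
    packer = _ParamPacker(model, estimate_f, estimate_tlag)
    x = _covariate_x(data, model)
    cache = {"phi": None}

    def objective(p):
        mu, omega, sig_prop, sig_add, exponents, tlag = packer.unpack(p)
        mu_i = _mu_matrix(mu, x, exponents, model.covariate_model)
        try:
            m2ll, phi = _laplace_m2ll(
                mu_i, omega, data, sig_prop, sig_add, model.residual_error,
                phi0=cache["phi"], tlag=tlag,
            )
        except (np.linalg.LinAlgError, FloatingPointError):  # pragma: no cover
            return 1e12
        cache["phi"] = phi
        return m2ll if np.isfinite(m2ll) else 1e12

    p0 = packer.pack(
        transform_theta(model.theta), model.omega_vector(),
        model.sigma_prop, model.sigma_add, model.exponents,
        tlag=0.01 if estimate_tlag else 0.0,
    )
    res = optimize.minimize(
        objective, p0, method="Nelder-Mead",
        options={"maxiter": max_iter, "maxfev": max_iter,
                 "xatol": 5e-4, "fatol": 5e-2, "adaptive": True},
    )
    if nm_restart:
        # one simplex restart from the optimum: Nelder-Mead routinely stalls
        # with a collapsed simplex, and a fresh one recovers the last
        # fraction of a percent
        res2 = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"maxiter": max(max_iter // 2, 200),
                     "maxfev": max(max_iter // 2, 200),
                     "xatol": 2e-4, "fatol": 1e-2, "adaptive": True},
        )
        if res2.fun <= res.fun:
            res = res2
    mu, omega, sig_prop, sig_add, exponents, tlag = packer.unpack(res.x)
    status = "converged" if res.success else "max_iter"
    return mu, omega, sig_prop, sig_add, exponents, tlag, res, status, packer, cache["phi"]


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def fit_population(
    data: pd.DataFrame | StackedData,
    model: PopulationModel,
    method: str = "SAEM",
    seed: int = 0,
    max_iter: Optional[object] = None,
    compute_rse: bool = False,
    compute_mofv: bool = True,
    n_is: int = 1000,
    estimate_tlag: bool = False,
    n_kernel: int = 3,
    nm_restart: bool = True,
) -> FitResult:
    """Simultaneous population fit of both routes.

    ``max_iter`` is ``(n_burn, n_smooth)`` for SAEM (default ``(400, 200)``)
    or the maximum number of objective evaluations for LAPLACE (default
    4000).  Everything stochastic is driven by ``seed``.
    """
    method = method.upper()
    if method not in ("SAEM", "LAPLACE", "SAEM+LAPLACE"):
        raise ValueError("method must be 'SAEM', 'LAPLACE' or 'SAEM+LAPLACE'")
    if method == "SAEM+LAPLACE":
        # stochastic stage for global movement, deterministic polish for the
        # weakly-informed fixed effects that SAEM moves slowly
        import dataclasses

        pre = fit_population(
            data, model, method="SAEM", seed=seed, max_iter=max_iter,
            compute_rse=False, compute_mofv=False, n_kernel=n_kernel,
        )
        polished_model = dataclasses.replace(
            model,
            theta=pre.theta,
            omega_sd={k: pre.omega_sd[k] for k in model.omega_sd},
            sigma_prop=max(pre.sigma_prop, 1e-6),
            sigma_add=pre.sigma_add if model.residual_error != "proportional" else model.sigma_add,
        )
        fit = fit_population(
            data, polished_model, method="LAPLACE", seed=seed, max_iter=None,
            compute_rse=compute_rse, compute_mofv=compute_mofv, n_is=n_is,
            estimate_tlag=estimate_tlag,
        )
        fit.method = "SAEM+LAPLACE"
        fit.trace = pre.trace
        return fit
    stacked = data if isinstance(data, StackedData) else stack_events(data)
    if stacked.n_subjects < 2:
        raise ValueError("population estimation needs at least 2 subjects")
    routes = stacked.routes_present
    estimate_f = routes == {"iv", "im"}
    if not estimate_f:
        logger.warning(
            "only %s data present; bioavailability fixed at its initial value",
            ",".join(sorted(routes)),
        )
    status = "converged"
    tlag = 0.0
    trace = None
    if method == "SAEM":
        if estimate_tlag:
            raise NotImplementedError("tlag estimation is only available with LAPLACE")
        if max_iter is None:
            n_burn, n_smooth = 400, 200
        else:
            n_burn, n_smooth = max_iter
        mu, omega, sig_prop, sig_add, exponents, trace, _phi = _fit_saem(
            stacked, model, seed, n_burn, n_smooth, n_kernel=n_kernel,
            estimate_f=estimate_f,
        )
        packer = _ParamPacker(model, estimate_f)
    else:
        mi = 4000 if max_iter is None else int(max_iter)
        mu, omega, sig_prop, sig_add, exponents, tlag, res, status, packer, _phi = (
            _fit_laplace(stacked, model, estimate_f, mi, estimate_tlag,
                         nm_restart=nm_restart)
        )

    x = _covariate_x(stacked, model)
    mu_i = _mu_matrix(mu, x, exponents, model.covariate_model)
    phi_hat, hess, _negpost, active = _map_phi(
        mu_i, omega, stacked, sig_prop, sig_add, model.residual_error, tlag=tlag,
    )
    eta_hat = phi_hat - mu_i
    ebe = pd.DataFrame({"ID": stacked.ids})
    for j, name in enumerate(PARAM_NAMES):
        ebe[f"eta_{name}"] = eta_hat[:, j]
        ebe[f"phi_{name}"] = phi_hat[:, j]

    if compute_mofv:
        mofv = _importance_m2ll(
            mu_i, omega, stacked, sig_prop, sig_add, model.residual_error,
            phi_hat, hess, active, seed=seed + 987, n_is=n_is, tlag=tlag,
        )
    else:
        mofv, _ = _laplace_m2ll(
            mu_i, omega, stacked, sig_prop, sig_add, model.residual_error,
            phi0=phi_hat, tlag=tlag,
        )
    n_params = packer.n_params
    aic = mofv + 2.0 * n_params

    omega_sd = {name: float(omega[j]) for j, name in enumerate(PARAM_NAMES)}
    omega_fixed = {name: name not in model.omega_sd for name in PARAM_NAMES}
    fit = FitResult(
        method=method,
        status=status,
        theta=untransform_mu(mu),
        omega_sd=omega_sd,
        omega_fixed=omega_fixed,
        sigma_prop=float(sig_prop),
        sigma_add=float(sig_add),
        residual_error=model.residual_error,
        covariate_model=model.covariate_model,
        ref_bw=model.ref_bw,
        exponents=tuple(float(e) for e in exponents),
        mofv=float(mofv),
        aic=float(aic),
        n_params=n_params,
        mu=mu,
        ebe=ebe,
        data_hash=stacked.hash(),
        n_subjects=stacked.n_subjects,
        n_obs=stacked.n_obs,
        seed=seed,
        trace=trace,
        tlag=float(tlag),
    )

    shr_eta, shr_eps = shrinkage(fit, stacked)
    fit.eta_shrinkage_pct = shr_eta
    fit.eps_shrinkage_pct = shr_eps

    if compute_rse:
        _attach_rse(fit, stacked, model, packer, estimate_f)
    return fit


def _attach_rse(fit, stacked, model, packer, estimate_f):
    """Finite-difference observed-information standard errors (RSE%)."""
    x = _covariate_x(stacked, model)
    omega0 = np.array([fit.omega_sd[name] for name in PARAM_NAMES])
    p_hat = packer.pack(
        fit.mu, omega0, fit.sigma_prop, fit.sigma_add, fit.exponents, fit.tlag
    )
    cache = {"phi": None}

    def objective(p):
        mu, omega, sig_prop, sig_add, exponents, tlag = packer.unpack(p)
        mu_i = _mu_matrix(mu, x, exponents, model.covariate_model)
        m2ll, phi = _laplace_m2ll(
            mu_i, omega, stacked, sig_prop, sig_add, model.residual_error,
            phi0=cache["phi"], tlag=tlag, tight=True,
        )
        cache["phi"] = phi
        return m2ll

    k = len(p_hat)
    h = 5e-3
    hess = np.empty((k, k))
    base_grad = np.empty(k)
    f_plus = np.empty(k)
    f_minus = np.empty(k)
    f0 = objective(p_hat)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h
        f_plus[i] = objective(p_hat + e)
        f_minus[i] = objective(p_hat - e)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                hess[i, i] = (f_plus[i] - 2.0 * f0 + f_minus[i]) / h**2
            else:
                e_i = np.zeros(k); e_i[i] = h
                e_j = np.zeros(k); e_j[j] = h
                f_pp = objective(p_hat + e_i + e_j)
                f_pm = objective(p_hat + e_i - e_j)
                f_mp = objective(p_hat - e_i + e_j)
                f_mm = objective(p_hat - e_i - e_j)
                hess[i, j] = hess[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4.0 * h**2)
    try:
        cov = 2.0 * np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        logger.warning("singular information matrix; RSE not reported")
        return
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    if np.any(np.diag(cov) < 0):
        logger.warning("information matrix not positive definite; RSE flagged")
    names = packer.full_names
    rse = {}
    theta_vals = fit.theta.as_dict()
    for name, se_j in zip(names, se):
        if name in PARAM_NAMES:
            if name == "f":
                f_val = theta_vals["f"]
                rse[name] = 100.0 * se_j * f_val * (1.0 - f_val) / f_val
            else:
                rse[name] = 100.0 * se_j  # log scale: SE_log ~ CV of estimate
        else:
            rse[name] = 100.0 * se_j  # log-scale omegas/sigmas, raw otherwise
    fit.rse_pct = rse
    fit.covariance = cov
    fit.param_order = names
    theta_idx = [i for i, nm in enumerate(names) if nm in PARAM_NAMES]
    sub = cov[np.ix_(theta_idx, theta_idx)]
    fit.condition_number = condition_number(_cov_to_corr(sub))


def _cov_to_corr(cov: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def condition_number(fit_or_corr) -> float:
    """Ratio of the largest to the smallest eigenvalue of the fixed-effect
    correlation matrix."""
    if isinstance(fit_or_corr, FitResult):
        return fit_or_corr.condition_number
    corr = np.asarray(fit_or_corr, dtype=float)
    eig = np.linalg.eigvalsh(corr)
    if eig[0] <= 0:
        logger.warning("correlation matrix not positive definite")
        return np.inf
    return float(eig[-1] / eig[0])


# ---------------------------------------------------------------------------
# diagnostics on a fit
# ---------------------------------------------------------------------------

def _fit_context(fit: FitResult, data: pd.DataFrame | StackedData):
    stacked = data if isinstance(data, StackedData) else stack_events(data)
    x = np.zeros(stacked.n_subjects)
    if fit.covariate_model != "none":
        x = np.log(stacked.bw / fit.ref_bw)
    mu_i = _mu_matrix(fit.mu, x, fit.exponents, fit.covariate_model)
    omega = np.array([fit.omega_sd[name] for name in PARAM_NAMES])
    return stacked, mu_i, omega


def shrinkage(
    fit: FitResult, data: pd.DataFrame | StackedData
) -> tuple[dict[str, float], float]:
    """Eta shrinkage per estimated IIV (100*(1 - SD(EBE)/omega)) and epsilon
    shrinkage (100*(1 - SD(IWRES)))."""
    stacked, mu_i, omega = _fit_context(fit, data)
    eta_cols = [f"eta_{name}" for name in PARAM_NAMES]
    eta = fit.ebe[eta_cols].to_numpy()
    out: dict[str, float] = {}
    for j, name in enumerate(PARAM_NAMES):
        if fit.omega_fixed[name]:
            continue
        if omega[j] <= 0:
            logger.warning("omega for %s is zero; eta shrinkage undefined", name)
            continue
        sd = float(np.std(eta[:, j], ddof=1)) if len(eta) > 1 else 0.0
        out[name] = 100.0 * (1.0 - sd / omega[j])
    phi_hat = fit.ebe[[f"phi_{name}" for name in PARAM_NAMES]].to_numpy()
    f_ind = _predict(phi_hat, stacked, fit.tlag)
    sd_res = _residual_sd(f_ind, fit.sigma_prop, fit.sigma_add, fit.residual_error)
    iwres = ((stacked.y - np.maximum(f_ind, _F_FLOOR)) / sd_res)[stacked.mask]
    eps = 100.0 * (1.0 - float(np.std(iwres, ddof=1))) if len(iwres) > 1 else np.nan
    return out, eps


def residual_diagnostics(
    fit: FitResult, data: pd.DataFrame | StackedData
) -> pd.DataFrame:
    """PRED/IPRED/IWRES/CWRES table, one row per observation.

    CWRES uses a first-order conditional linearization of the model around
    the empirical Bayes etas.
    """
    stacked, mu_i, omega = _fit_context(fit, data)
    phi_hat = fit.ebe[[f"phi_{name}" for name in PARAM_NAMES]].to_numpy()
    eta_hat = phi_hat - mu_i
    pred = _predict(mu_i, stacked, fit.tlag)
    ipred = np.maximum(_predict(phi_hat, stacked, fit.tlag), _F_FLOOR)
    sd_ind = _residual_sd(ipred, fit.sigma_prop, fit.sigma_add, fit.residual_error)
    iwres = (stacked.y - ipred) / sd_ind

    n, m = stacked.y.shape
    h = 1e-5
    jac = np.empty((n, m, len(PARAM_NAMES)))
    for j in range(len(PARAM_NAMES)):
        phi_p = phi_hat.copy()
        phi_p[:, j] += h
        jac[:, :, j] = (_predict(phi_p, stacked, fit.tlag) - ipred) / h
    omega_mat = np.diag(omega**2)
    rows = []
    for i in range(n):
        sel = stacked.mask[i]
        g = jac[i][sel]
        f_lin = ipred[i][sel] - g @ eta_hat[i]
        v_res = _residual_sd(
            ipred[i][sel], fit.sigma_prop, fit.sigma_add, fit.residual_error
        ) ** 2
        cov = g @ omega_mat @ g.T + np.diag(v_res)
        resid = stacked.y[i][sel] - f_lin
        try:
            chol = np.linalg.cholesky(cov)
            cwres = solve_triangular(chol, resid, lower=True)
        except np.linalg.LinAlgError:  # pragma: no cover
            cwres = np.full(sel.sum(), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "ID": stacked.ids[i],
                    "TIME": stacked.t[i][sel],
                    "ROUTE": np.where(stacked.is_iv[i][sel], 1, 2),
                    "DV": stacked.y[i][sel],
                    "PRED": pred[i][sel],
                    "IPRED": ipred[i][sel],
                    "IWRES": iwres[i][sel],
                    "CWRES": cwres,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelComparison:
    preferred: str  # "reduced" | "full" | "a" | "b"
    criterion: str  # "lrt" | "aic"
    delta: float
    threshold: float


def compare_models(
    fit_reduced: FitResult, fit_full: FitResult, df_extra: int
) -> ModelComparison:
    """Nested comparison by the chi-square MOFV drop at p < 0.005 (7.879 for
    one degree of freedom); non-nested (df_extra == 0) by lower AIC."""
    if fit_reduced.data_hash != fit_full.data_hash:
        raise ValueError("fits were not obtained on the same data; refusing")
    if df_extra < 0:
        raise ValueError("df_extra must be >= 0")
    if df_extra == 0:
        preferred = "a" if fit_reduced.aic <= fit_full.aic else "b"
        return ModelComparison(
            preferred=preferred, criterion="aic",
            delta=fit_reduced.aic - fit_full.aic, threshold=0.0,
        )
    threshold = float(stats.chi2.ppf(0.995, df_extra))
    delta = fit_reduced.mofv - fit_full.mofv
    preferred = "full" if delta > threshold else "reduced"
    return ModelComparison(
        preferred=preferred, criterion="lrt", delta=delta, threshold=threshold
    )


# ---------------------------------------------------------------------------
# initial estimates
# ---------------------------------------------------------------------------

def initial_from_nca(events: pd.DataFrame) -> ThetaFixed:
    """Rough typical-value initials derived from a per-subject NCA.

    Clearance from IV dose/AUC, the central volume from the back-extrapolated
    initial volume, the peripheral volume from Vdarea minus Vc (floored), a
    distribution clearance an order of magnitude above CL, Ka from the median
    IM Tmax and F from the dose-normalized AUC ratio.
    """
    from .nca import run_nca

    table = run_nca(events, route="both", per_kg=False)
    iv = table[(table["route"] == "iv") & (table["status"] == "ok")]
    im = table[(table["route"] == "im") & (table["status"] == "ok")]
    if iv.empty:
        raise ValueError("NCA initials need at least one IV profile")
    cl = float(iv["cl"].mean())
    vc = float(iv["vi"].mean()) if iv["vi"].notna().any() else float(iv["vss"].mean())
    vd = float(iv["vdarea"].mean())
    vp = max(vd - vc, 0.2 * vc)
    cld = 10.0 * cl
    if not im.empty and im["tmax"].notna().any():
        ka = math.log(3.0) / float(im["tmax"].median())
    else:
        ka = 1.0
    f = float(np.clip(im["f_pct"].mean() / 100.0, 0.05, 0.99)) if not im.empty else 0.9
    return ThetaFixed(cl=cl, vc=vc, cld=cld, vp=vp, ka=ka, f=f)
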