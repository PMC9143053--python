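"""Dataset readers/writers, pipeline configuration, and the full analysis
pipeline (simulate -> NCA -> population fit -> VPC -> regimen scoring)."""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .datagen import GenerativeModel, StudyDesign, generate_study
from .diagnostics import vpc
from .model import ThetaFixed
from .nca import nca_summary, run_nca
from .nlme import PopulationModel, fit_population
from .regimen import RegimenSpec, rank_regimens, simulate_regimen, window_report

__all__ = [
    "EVENT_COLUMNS",
    "read_events",
    "write_events",
    "PipelineConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["ID", "OCC", "TIME", "AMT", "DV", "EVID", "ROUTE", "BW"]


def read_events(path) -> pd.DataFrame:
    """Read and validate an event table CSV.

    Columns: ID, OCC, TIME, AMT, DV, EVID (1 dose / 0 observation / 2 blank),
    ROUTE (1 IV / 2 IM), BW.  Dose rows must have empty DV; rows with
    negative times are rejected with a report.
    """
    table = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table is missing column(s): {', '.join(missing)}")
    bad_dose_dv = table[(table["EVID"] == 1) & table["DV"].notna()]
    if not bad_dose_dv.empty:
        raise ValueError(
            "dose rows must have empty DV; offending row index(es): "
            f"{list(bad_dose_dv.index)}"
        )
    negative = table[table["TIME"] < 0]
    if not negative.empty:
        logger.warning(
            "rejecting %d row(s) with negative TIME: %s",
            len(negative), list(negative.index),
        )
        table = table.drop(index=negative.index).reset_index(drop=True)
    obs = table[table["EVID"] == 0]
    logger.info(
        "read %d rows: %d IV + %d IM observations",
        len(table),
        int((obs["ROUTE"] == 1).sum()),
        int((obs["ROUTE"] == 2).sum()),
    )
    return table


def write_events(table: pd.DataFrame, path) -> None:
    """Write an event table CSV (full double precision, empty DV on doses)."""
    out = table[EVENT_COLUMNS].copy()
    out.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Everything needed for a fully deterministic end-to-end run."""

    seed: int = 1
    design: StudyDesign = field(default_factory=StudyDesign)
    generative: GenerativeModel = field(default_factory=GenerativeModel.reference)
    fit_method: str = "SAEM+LAPLACE"
    fit_seed: int = 1
    max_iter: Optional[tuple[int, int]] = None
    initial_theta: Optional[ThetaFixed] = None
    omega_sd_init: dict = field(
        default_factory=lambda: {"cl": 0.3, "vc": 0.3, "ka": 0.5}
    )
    sigma_prop_init: float = 0.3
    vpc_replicates: int = 1000
    vpc_seed: int = 1
    vpc_pi: float = 0.95
    regimens: list[RegimenSpec] = field(
        default_factory=lambda: [
            RegimenSpec(4.0, "im", tau, 10, 31.5) for tau in (8.0, 12.0, 24.0)
        ] + [
            RegimenSpec(3.0, "iv", tau, 10, 31.5) for tau in (8.0, 12.0, 24.0)
        ]
    )
    window: tuple[float, float] = (15.0, 20.0)
    out_dir: str = "pipeline_run"

    def to_yaml(self, path) -> None:
        payload = {
            "seed": self.seed,
            "design": asdict(self.design),
            "generative": {
                "theta": self.generative.theta.as_dict(),
                "omega_sd": dict(self.generative.omega_sd),
                "fixed_omega_sd": self.generative.fixed_omega_sd,
                "sigma_prop": self.generative.sigma_prop,
            },
            "fit_method": self.fit_method,
            "fit_seed": self.fit_seed,
            "max_iter": list(self.max_iter) if self.max_iter else None,
            "initial_theta": self.initial_theta.as_dict() if self.initial_theta else None,
            "omega_sd_init": dict(self.omega_sd_init),
            "sigma_prop_init": self.sigma_prop_init,
            "vpc_replicates": self.vpc_replicates,
            "vpc_seed": self.vpc_seed,
            "vpc_pi": self.vpc_pi,
            "regimens": [
                {
                    "dose_per_kg": r.dose_per_kg,
                    "route": r.route.value,
                    "tau": r.tau,
                    "n_doses": r.n_doses,
                    "bodyweight": r.bodyweight,
                }
                for r in self.regimens
            ],
            "window": list(self.window),
            "out_dir": self.out_dir,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        design = payload.get("design", {})
        for key in ("iv_times", "im_times", "bw_range"):
            if key in design:
                design[key] = tuple(design[key])
        gen = payload.get("generative", {})
        generative = GenerativeModel(
            theta=ThetaFixed(**gen["theta"]),
            omega_sd=gen.get("omega_sd", {}),
            fixed_omega_sd=gen.get("fixed_omega_sd", 0.15),
            sigma_prop=gen.get("sigma_prop", 0.0),
        ) if gen else GenerativeModel.reference()
        init = payload.get("initial_theta")
        return cls(
            seed=payload.get("seed", 1),
            design=StudyDesign(**design) if design else StudyDesign(),
            generative=generative,
            fit_method=payload.get("fit_method", "SAEM+LAPLACE"),
            fit_seed=payload.get("fit_seed", 1),
            max_iter=tuple(payload["max_iter"]) if payload.get("max_iter") else None,
            initial_theta=ThetaFixed(**init) if init else None,
            omega_sd_init=payload.get("omega_sd_init", {"cl": 0.3, "vc": 0.3, "ka": 0.5}),
            sigma_prop_init=payload.get("sigma_prop_init", 0.3),
            vpc_replicates=payload.get("vpc_replicates", 1000),
            vpc_seed=payload.get("vpc_seed", 1),
            vpc_pi=payload.get("vpc_pi", 0.95),
            regimens=[
                RegimenSpec(
                    dose_per_kg=r["dose_per_kg"], route=r["route"], tau=r["tau"],
                    n_doses=r["n_doses"], bodyweight=r["bodyweight"],
                )
                for r in payload.get("regimens", [])
            ] or cls().regimens,
            window=tuple(payload.get("window", (15.0, 20.0))),
            out_dir=payload.get("out_dir", "pipeline_run"),
        )


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> Path:
    """Run the whole analysis on synthetic data; returns the run directory.

    Artifacts: events.csv, nca.csv, nca_summary.csv, fit.json, fit_table.csv,
    vpc.csv, regimen_report.csv and run_log.json.  Fully deterministic for a
    given config; stage failures abort with the stage named, retaining the
    artifacts produced so far.
    """
    run_dir = Path(out_dir or config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seeds": {
            "study": config.seed,
            "fit": config.fit_seed,
            "vpc": config.vpc_seed,
        },
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                log["stages"][name] = {"status": "failed", "error": str(exc)}
                (run_dir / "run_log.json").write_text(json.dumps(log, indent=2))
                raise PipelineError(name, exc) from exc
            log["stages"][name] = {
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
            return result
        return wrap

    events = stage("simulate")(
        lambda: generate_study(config.design, config.generative, config.seed)
    )
    write_events(events, run_dir / "events.csv")

    def _nca():
        per_subject = run_nca(events, route="both", per_kg=False)
        per_subject.to_csv(run_dir / "nca.csv", index=False)
        nca_summary(per_subject).to_csv(run_dir / "nca_summary.csv", index=False)
        return per_subject

    stage("nca")(_nca)

    def _fit():
        model = PopulationModel(
            theta=config.initial_theta or config.generative.theta,
            omega_sd=config.omega_sd_init,
            sigma_prop=config.sigma_prop_init,
        )
        fit = fit_population(
            events, model, method=config.fit_method, seed=config.fit_seed,
            max_iter=config.max_iter,
        )
        (run_dir / "fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
        fit.estimates_table().to_csv(run_dir / "fit_table.csv", index=False)
        return fit

    fit = stage("fit")(_fit)

    def _vpc():
        summary = vpc(
            fit, events, n_replicates=config.vpc_replicates,
            seed=config.vpc_seed, pi=config.vpc_pi,
        )
        summary.table.to_csv(run_dir / "vpc.csv", index=False)
        return summary

    stage("vpc")(_vpc)

    def _regimens():
        reports = []
        for spec in config.regimens:
            profile, info = simulate_regimen(spec, fit.theta)
            reports.append(window_report(profile, config.window, regimen=spec))
        ranked = rank_regimens(reports)
        table = pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "regimen": r.regimen.label(),
                    "route": r.regimen.route.value,
                    "tau_h": r.regimen.tau,
                    "dose_per_kg": r.regimen.dose_per_kg,
                    "fraction_in_window": r.fraction_in_window,
                    "cmax_ss": r.cmax_ss,
                    "cmin_ss": r.cmin_ss,
                }
                for i, r in enumerate(ranked)
            ]
        )
        table.to_csv(run_dir / "regimen_report.csv", index=False)
        return ranked

    stage("regimens")(_regimens)

    (run_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return run_dir
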