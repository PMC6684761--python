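"""End-to-end orchestration: generate -> solve -> invert -> fatigue.

A :class:`RunConfig` (built in code or loaded from YAML) drives the full
chain and writes a reproducible run directory: the gait trial, the
per-sample actuation solution, the stimulation profiles, optional
fatigue snapshots, and a manifest carrying a content hash of the
configuration plus residual statistics. Identical config + seed yields
byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, CoactError
from .fatigue import FatigueModel, FESConfig, fatigue_compensated_solve
from .fes_synthesis import FESProfile
from .gait_model import (GaitTrial, MuscleGeometry, PlanarSegmentModel,
                         generate_normative_gait, read_trial, write_trial)
from .load_sharing import LoadSharingOptions, solve_trajectory
from .muscle_model import max_achievable_forces
from .muscles import default_muscle_params, load_muscle_params

log = logging.getLogger("coact")


@dataclass(frozen=True)
class SyntheticTrialConfig:
    n_samples: int = 101
    cycle_duration: float = 1.2
    subject_mass: float = 72.6
    subject_height: float = 1.70
    variability: float = 0.0


@dataclass(frozen=True)
class FatigueRunConfig:
    enabled: bool = False
    kind: str = "exponential"
    horizon: float = 180.0
    snapshot_times: tuple[float, ...] = (0.0, 60.0, 120.0, 180.0)


@dataclass(frozen=True)
class RunConfig:
    """Schema-validated configuration of one pipeline run."""

    trial_file: str | None = None          # path; None -> synthetic
    trial_dialect: str = "csv"
    synthetic: SyntheticTrialConfig = field(default_factory=SyntheticTrialConfig)
    muscle_params_file: str | None = None
    load_sharing: LoadSharingOptions = field(default_factory=LoadSharingOptions)
    fes: FESConfig = field(default_factory=FESConfig)
    fatigue: FatigueRunConfig = field(default_factory=FatigueRunConfig)
    outdir: str = "coact_run"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        if not isinstance(doc, dict):
            raise ConfigurationError("run config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ConfigurationError(f"unknown config key(s): {sorted(bad)}")
        sub = {}
        for key, sub_cls in (("synthetic", SyntheticTrialConfig),
                             ("load_sharing", LoadSharingOptions),
                             ("fes", FESConfig),
                             ("fatigue", FatigueRunConfig)):
            if key in doc:
                val = doc[key]
                if not isinstance(val, dict):
                    raise ConfigurationError(f"{key} must be a mapping")
                bad = set(val) - set(sub_cls.__dataclass_fields__)
                if bad:
                    raise ConfigurationError(
                        f"unknown {key} key(s): {sorted(bad)}")
                for tup_key in ("To_max", "To_min", "snapshot_times"):
                    if tup_key in val and val[tup_key] is not None:
                        val[tup_key] = tuple(val[tup_key])
                sub[key] = sub_cls(**val)
        merged = {**doc, **sub}
        return cls(**merged)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _load_trial(config: RunConfig) -> GaitTrial:
    if config.trial_file is not None:
        return read_trial(config.trial_file, dialect=config.trial_dialect)
    sc = config.synthetic
    model = PlanarSegmentModel.default_adult(total_mass=sc.subject_mass,
                                             height=sc.subject_height)
    return generate_normative_gait(model, MuscleGeometry.default(),
                                   n_samples=sc.n_samples,
                                   cycle_duration=sc.cycle_duration,
                                   seed=config.seed,
                                   variability=sc.variability)


def _write_profiles(profiles: dict[str, FESProfile], time, path) -> None:
    cols: dict[str, np.ndarray] = {"time": np.asarray(time)}
    for m, prof in profiles.items():
        cols[f"{m}_cmd"] = prof.command
        cols[f"{m}_mask"] = prof.mask.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def run_pipeline(config: RunConfig) -> str:
    """Execute all pipeline stages; returns the run directory path.

    Stage failures propagate as :class:`~coact.errors.CoactError`
    prefixed with the stage name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except CoactError as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    trial = stage("trial", _load_trial, config)
    write_trial(trial, os.path.join(outdir, "trial.csv"), dialect="csv")

    params = (load_muscle_params(config.muscle_params_file)
              if config.muscle_params_file else default_muscle_params())
    maxforce = stage("max_forces", max_achievable_forces, trial, params)
    solution = stage("load_sharing", solve_trajectory, trial, maxforce,
                     config.load_sharing, params=params)
    solution.write(outdir, prefix="solution")

    from .fatigue import _invert_profiles
    profiles = stage("fes", _invert_profiles, solution, params, config.fes,
                     trial.dt)
    _write_profiles(profiles, trial.time, os.path.join(outdir, "fes.csv"))
    with open(os.path.join(outdir, "fes_meta.json"), "w") as fh:
        json.dump({"mode": config.fes.mode,
                   "fixed_value": config.fes.fixed_value,
                   "units": ("Hz" if config.fes.mode == "frequency_modulated"
                             else "mA"),
                   "u_tr": config.fes.u_tr, "u_sat": config.fes.u_sat,
                   "k2_ratio": config.fes.k2_ratio, "f_cf": config.fes.f_cf,
                   "R": config.fes.R}, fh, indent=2, sort_keys=True)

    if config.fatigue.enabled:
        model = FatigueModel(kind=config.fatigue.kind)
        run = stage("fatigue", fatigue_compensated_solve, trial, maxforce,
                    config.load_sharing, model,
                    horizon=config.fatigue.horizon,
                    snapshot_times=config.fatigue.snapshot_times,
                    params=params, fes=config.fes)
        run.write(os.path.join(outdir, "fatigue"))

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_sha256": config.content_hash(),
        "seed": config.seed,
        "n_samples": int(trial.n_samples),
        "residual_max": float(np.max(solution.residuals)),
        "residual_mean": float(np.mean(solution.residuals)),
        "tolerance_factor": config.load_sharing.tol_factor,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    log.info("run complete: %s", outdir)
    return outdir


def summarize_run(run_dir: str, write: bool = True) -> dict[str, pd.DataFrame]:
    """Aggregate a completed run into summary tables.

    Returns (and optionally writes) a torque-decomposition table per
    joint (total, motor, FES; one row per snapshot where a fatigue run
    exists) and per-muscle activation and stimulation envelopes.
    """
    sol_path = os.path.join(run_dir, "solution.csv")
    if not os.path.exists(sol_path):
        raise ConfigurationError(f"incomplete run: {sol_path} missing")
    sol = pd.read_csv(sol_path)

    def decompose(df: pd.DataFrame, label: str) -> pd.DataFrame:
        rows = []
        for j in ("hip", "knee", "ankle"):
            rows.append({
                "snapshot": label, "joint": j,
                "total_rms": float(np.sqrt(np.mean(df[f"T_{j}"] ** 2))),
                "motor_rms": float(np.sqrt(np.mean(df[f"To_{j}"] ** 2))),
                "fes_rms": float(np.sqrt(np.mean(df[f"Tfes_{j}"] ** 2))),
                "motor_plus_fes_minus_total_max": float(
                    np.max(np.abs(df[f"To_{j}"] + df[f"Tfes_{j}"]
                                  - df[f"T_{j}"]))),
            })
        return pd.DataFrame(rows)

    torque_tables = [decompose(sol, "unfatigued")]
    fat_dir = os.path.join(run_dir, "fatigue")
    if os.path.isdir(fat_dir):
        for fn in sorted(os.listdir(fat_dir)):
            if fn.startswith("snapshot_") and fn.endswith(".csv"):
                label = fn[len("snapshot_"):-len(".csv")]
                torque_tables.append(
                    decompose(pd.read_csv(os.path.join(fat_dir, fn)), label))
    torque = pd.concat(torque_tables, ignore_index=True)

    act_cols = [c for c in sol.columns if c.startswith("a_")]
    envelopes = pd.DataFrame({
        "muscle": [c[2:] for c in act_cols],
        "a_min": [float(sol[c].min()) for c in act_cols],
        "a_mean": [float(sol[c].mean()) for c in act_cols],
        "a_max": [float(sol[c].max()) for c in act_cols],
    })
    fes_path = os.path.join(run_dir, "fes.csv")
    if os.path.exists(fes_path):
        fes = pd.read_csv(fes_path)
        envelopes["cmd_max"] = [
            float(fes[f"{m}_cmd"].max()) if f"{m}_cmd" in fes else np.nan
            for m in envelopes["muscle"]]

    out = {"torque_decomposition": torque, "envelopes": envelopes}
    if write:
        for name, df in out.items():
            df.to_csv(os.path.join(run_dir, f"summary_{name}.csv"),
                      index=False, float_format="%.17g")
    return out
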