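"""FES-induced fatigue models and fatigue-compensated re-planning.

Prolonged electrical stimulation recruits fast, fatigable fibers
indiscriminately, so the force a muscle can produce decays over minutes.
Two force-capacity models are provided, both expressed as a
multiplicative scale psi in (0, 1] on the maximally achievable force:

* ``exponential`` — time-driven decay ``psi(t) = exp(-C1 t - C2) + C3``,
  identical for every muscle, calibrated (C1 = 0.02 1/s, C2 = 0.3,
  C3 = 0.2) to an ~80 % peak-force loss over three minutes with a
  gentle slope. Note psi(0) = exp(-C2) + C3 < 1: stimulation starts
  from a slightly sub-maximal capacity. A normalize-to-one flag exists
  but is off by default.
* ``riener`` — activation-driven first-order fatigue/recovery dynamics
  ``dpsi/dt = (psi_min - psi) a / T_fat + (1 - psi) (1 - a) / T_rec``,
  per muscle, so heavily stimulated muscles fatigue earlier and idle
  muscles recover. The shipped constants (psi_min = 0, T_fat = 18 s,
  T_rec = 76 s) are external-literature defaults — override encouraged.

Fatigue-compensated planning repeats the gait cycle over a horizon,
re-solving the load sharing each evaluated cycle with the muscle cost
terms weighted by psi and the available muscle force scaled to
psi * f*; the FES profiles are then re-inverted from the new
activations. Total joint torque is preserved — the motors absorb
whatever the fatigued muscles can no longer deliver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InfeasibleError, InvalidArgumentError
from .fes_synthesis import (FESProfile, FrequencyParams, LinearBlockParams,
                            RecruitmentParams, calibrate_frequency_params,
                            synthesize_fes)
from .gait_model import GaitTrial
from .load_sharing import (ActuationSolution, LoadSharingOptions,
                           MaxForceTrajectory, solve_trajectory)
from .muscle_model import MuscleParams


@dataclass(frozen=True)
class FatigueModel:
    """Fatigue-model identity and constants (see module docstring)."""

    kind: str = "exponential"
    C1: float = 0.02      # 1/s
    C2: float = 0.3
    C3: float = 0.2
    psi_min: float = 0.0
    T_fat: float = 18.0   # s
    T_rec: float = 76.0   # s
    normalize_at_zero: bool = False

    def __post_init__(self):
        if self.kind not in ("exponential", "riener"):
            raise InvalidArgumentError(f"unknown fatigue kind: {self.kind!r}")
        if self.C1 <= 0:
            raise InvalidArgumentError("C1 must be > 0")
        if not 0.0 <= self.C3 < 1.0:
            raise InvalidArgumentError("C3 must lie in [0, 1)")
        if not 0.0 <= self.psi_min < 1.0:
            raise InvalidArgumentError("psi_min must lie in [0, 1)")
        if self.T_fat <= 0 or self.T_rec <= 0:
            raise InvalidArgumentError("T_fat and T_rec must be > 0")


@dataclass
class FatigueState:
    """Per-muscle capacity scale over the simulation horizon."""

    time: np.ndarray           # (n_t,) s, cycle starts
    psi: np.ndarray            # (n_t, n_muscles)
    model: FatigueModel
    muscle_names: tuple[str, ...]

    def __post_init__(self):
        if np.any(self.psi <= 0) or np.any(self.psi > 1.0 + 1e-12):
            raise InvalidArgumentError("psi must lie in (0, 1]")


def psi_exponential(t, m: FatigueModel):
    """Time-driven capacity ``exp(-C1 t - C2) + C3`` (strictly decreasing
    toward the asymptote C3)."""
    if m.kind != "exponential":
        raise InvalidArgumentError("model kind is not 'exponential'")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidArgumentError("time must be >= 0")
    psi = np.exp(-m.C1 * t - m.C2) + m.C3
    if m.normalize_at_zero:
        psi = psi / (np.exp(-m.C2) + m.C3)
    return psi


def psi_riener(a, m: FatigueModel, psi0: float = 1.0,
               dt: float = 0.01) -> np.ndarray:
    """Integrate the activation-driven fatigue/recovery dynamics.

    The activation is held piecewise-constant over each step, for which
    the dynamics are linear with constant coefficients; each step uses
    the exact exponential update (fixed point ``psi*`` approached at
    rate ``a/T_fat + (1-a)/T_rec``). Full drive (a = 1) relaxes toward
    ``psi_min`` with time constant T_fat; rest relaxes toward 1 with
    time constant T_rec.
    """
    if m.kind != "riener":
        raise InvalidArgumentError("model kind is not 'riener'")
    a = np.asarray(a, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise InvalidArgumentError("activation must lie in [0, 1]")
    if not m.psi_min <= psi0 <= 1.0:
        raise InvalidArgumentError("psi0 must lie in [psi_min, 1]")
    if dt <= 0:
        raise InvalidArgumentError("dt must be > 0")
    rate = a / m.T_fat + (1.0 - a) / m.T_rec
    drive = m.psi_min * a / m.T_fat + (1.0 - a) / m.T_rec
    psi = np.empty_like(a)
    psi[0] = psi0
    decay = np.exp(-rate * dt)
    for i in range(1, len(a)):
        r, d = rate[i - 1], drive[i - 1]
        target = d / r if r > 0 else psi[i - 1]
        psi[i] = target + (psi[i - 1] - target) * decay[i - 1]
    return psi


@dataclass
class FatigueSnapshot:
    """Re-planned co-actuation at one instant of the fatigue horizon."""

    time: float
    psi: np.ndarray                       # (n_muscles,)
    solution: ActuationSolution
    fes_profiles: dict[str, FESProfile] | None = None


@dataclass
class FatigueRun:
    snapshots: list[FatigueSnapshot]
    state: FatigueState
    model: FatigueModel
    horizon: float

    def write(self, directory) -> None:
        """Per-snapshot solution CSVs, FES command CSVs and a manifest."""
        import json
        import os

        import pandas as pd

        os.makedirs(directory, exist_ok=True)
        for snap in self.snapshots:
            tag = f"t{int(round(snap.time)):04d}s"
            snap.solution.write(directory, prefix=f"snapshot_{tag}")
            if snap.fes_profiles:
                cols = {"time": snap.solution.time}
                for m, prof in snap.fes_profiles.items():
                    cols[f"{m}_cmd"] = prof.command
                    cols[f"{m}_mask"] = prof.mask.astype(int)
                pd.DataFrame(cols).to_csv(
                    os.path.join(directory, f"fes_{tag}.csv"),
                    index=False, float_format="%.17g")
        manifest = {
            "model": {"kind": self.model.kind, "C1": self.model.C1,
                      "C2": self.model.C2, "C3": self.model.C3,
                      "psi_min": self.model.psi_min,
                      "T_fat": self.model.T_fat, "T_rec": self.model.T_rec},
            "horizon_s": self.horizon,
            "snapshot_times_s": [s.time for s in self.snapshots],
        }
        with open(os.path.join(directory, "fatigue_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


@dataclass(frozen=True)
class FESConfig:
    """How to re-invert stimulation profiles at each snapshot."""

    mode: str = "amplitude_modulated"
    fixed_value: float = 30.0        # Hz in amplitude mode, mA in frequency mode
    u_tr: float = 20.0
    u_sat: float = 40.0
    k2_ratio: float = 1.2
    f_cf: float = 30.0
    R: float = 15.0

    def recruitment(self) -> RecruitmentParams:
        return RecruitmentParams(u_tr=self.u_tr, u_sat=self.u_sat)

    def frequency(self) -> FrequencyParams:
        return calibrate_frequency_params(self.k2_ratio, self.f_cf, self.R)


def _invert_profiles(solution: ActuationSolution, params, fes: FESConfig,
                     dt: float) -> dict[str, FESProfile]:
    rp = fes.recruitment()
    fp = fes.frequency()
    by_name = {p.name: p for p in params}
    out = {}
    for i, m in enumerate(solution.muscle_names):
        lbp = LinearBlockParams.from_muscle(by_name[m])
        out[m] = synthesize_fes(solution.activations[:, i], lbp, rp, fp,
                                dt=dt, mode=fes.mode,
                                fixed_value=fes.fixed_value,
                                time=solution.time, muscle=m)
    return out


def fatigue_compensated_solve(trial: GaitTrial,
                              maxforce: MaxForceTrajectory,
                              options: LoadSharingOptions,
                              model: FatigueModel,
                              horizon: float = 180.0,
                              snapshot_times=(0.0, 60.0, 120.0, 180.0),
                              params: list[MuscleParams] | None = None,
                              fes: FESConfig | None = FESConfig(),
                              riener_cycle_stride: int = 1) -> FatigueRun:
    """Re-plan the co-actuation over a multi-cycle fatigue horizon.

    The trial's cycle repeats back to back over ``horizon`` seconds;
    psi is held constant within a cycle and updated between cycles.

    For the exponential model psi depends on time only, so exactly the
    cycles containing the requested snapshot times are solved (skipped
    cycles cannot influence later ones). For the Riener model psi is
    driven by the solved activations, so cycles are processed in order;
    ``riener_cycle_stride`` > 1 holds each solved cycle's activation
    pattern for that many cycles to trade accuracy for speed.

    Raises :class:`InfeasibleError` naming the first failing time when
    fatigue erodes capacity past what motors can compensate.
    """
    if params is None:
        from .muscles import default_muscle_params
        params = default_muscle_params()
    T_cyc = trial.cycle_duration
    n_cycles = int(round(horizon / T_cyc))
    if abs(n_cycles * T_cyc - horizon) > 1e-6 * max(horizon, 1.0):
        raise InvalidArgumentError(
            "horizon must be an integer multiple of the cycle duration")
    snapshot_times = sorted(set(float(t) for t in snapshot_times))
    if snapshot_times[0] < 0 or snapshot_times[-1] > horizon:
        raise InvalidArgumentError("snapshot times must lie in [0, horizon]")
    # snap each requested time to the start of its containing cycle
    snap_cycles = sorted(set(min(int(t // T_cyc), n_cycles - 1)
                             for t in snapshot_times))
    n_m = len(params)
    names = tuple(p.name for p in params)
    dt = trial.dt

    snapshots: list[FatigueSnapshot] = []
    psi_times: list[float] = []
    psi_hist: list[np.ndarray] = []

    def solve_cycle(psi_vec, t0):
        try:
            return solve_trajectory(trial, maxforce, options, params=params,
                                    psi=psi_vec)
        except InfeasibleError as exc:
            raise InfeasibleError(
                f"capacity shortfall at t = {t0:.3f} s: {exc}",
                gap=exc.gap, samples=exc.samples) from exc

    if model.kind == "exponential":
        for c in snap_cycles:
            t0 = c * T_cyc
            psi_vec = np.full(n_m, float(psi_exponential(t0, model)))
            sol = solve_cycle(psi_vec, t0)
            profiles = _invert_profiles(sol, params, fes, dt) if fes else None
            snapshots.append(FatigueSnapshot(time=t0, psi=psi_vec,
                                             solution=sol,
                                             fes_profiles=profiles))
        # closed-form state at every cycle start over the horizon
        t_all = np.arange(n_cycles + 1) * T_cyc
        psi_all = np.tile(psi_exponential(t_all, model)[:, None], (1, n_m))
        psi_times = list(t_all)
        psi_hist = list(psi_all)
    else:
        psi_vec = np.ones(n_m)
        stride = max(1, int(riener_cycle_stride))
        c = 0
        sol = None
        while c < n_cycles:
            t0 = c * T_cyc
            sol = solve_cycle(psi_vec, t0)
            if c in snap_cycles:
                profiles = _invert_profiles(sol, params, fes, dt) if fes else None
                snapshots.append(FatigueSnapshot(time=t0, psi=psi_vec.copy(),
                                                 solution=sol,
                                                 fes_profiles=profiles))
            psi_times.append(t0)
            psi_hist.append(psi_vec.copy())
            # advance psi over `stride` cycles driven by this activation
            reps = min(stride, n_cycles - c)
            a_rep = np.tile(sol.activations[:-1], (reps, 1))
            a_rep = np.vstack([a_rep, sol.activations[-1:]])
            for j in range(n_m):
                psi_vec[j] = psi_riener(a_rep[:, j], model,
                                        psi0=psi_vec[j], dt=dt)[-1]
            psi_vec = np.clip(psi_vec, max(model.psi_min, 1e-9), 1.0)
            c += reps
        psi_times.append(n_cycles * T_cyc)
        psi_hist.append(psi_vec.copy())

    state = FatigueState(time=np.asarray(psi_times),
                         psi=np.asarray(psi_hist), model=model,
                         muscle_names=names)
    return FatigueRun(snapshots=snapshots, state=state, model=model,
                      horizon=horizon)
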