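"""Hill-type rigid-tendon muscle mechanics and activation dynamics.

With a rigid tendon the fiber state is fully determined by the recorded
musculotendon kinematics, so the contraction dynamics degenerate to an
algebraic Hill relation evaluated sample-wise. The first step of the
physiological static optimization — integrating the contraction dynamics
at full activation — therefore reduces to evaluating
``hill_force(a=1, ...)`` along the trial, which yields the trajectory of
maximally achievable muscle force ``f*(t)`` and its cycle maximum
``f_max`` used as cost normalizers downstream.

Curve forms (all shape constants configurable per muscle):

* active force-length: Gaussian, ``fl(l) = exp(-((l-1)/w)^2)``, peaking
  at 1 at the optimal fiber length;
* force-velocity: Hill hyperbola on the shortening side,
  ``fv(v) = (1+v)/(1-v/af)`` for v in [-1, 0] (v normalized to vmax,
  shortening negative), with a C1-smooth saturating eccentric branch
  approaching ``fv_ecc_max``;
* passive: exponential toe curve, zero at and below optimal length.

Pennation is neglected (0 deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, SchemaError
from .gait_model import GaitTrial


@dataclass(frozen=True)
class MuscleParams:
    """Per-muscle physiological constants.

    ``vmax`` is the maximum shortening velocity in optimal fiber lengths
    per second. ``T_rise``/``T_fall`` parameterize the physiological
    excitation-to-activation dynamics; ``T_e`` is the excitation time
    constant of the artificially stimulated muscle (second-order FES
    activation block).
    """

    name: str
    f0: float                     # N, max isometric force
    l0: float                     # m, optimal fiber length
    vmax: float = 10.0            # l0/s
    fl_width: float = 0.45        # dimensionless Gaussian width
    fv_shape: float = 0.25        # Hill curvature a/f0
    fv_ecc_max: float = 1.4       # eccentric force plateau (x f0)
    passive_strain: float = 0.6   # strain at which fp reaches 1
    passive_exponent: float = 4.0
    T_rise: float = 0.022         # s
    T_fall: float = 0.2           # s
    T_e: float = 0.01             # s

    def __post_init__(self):
        if self.f0 <= 0 or self.l0 <= 0 or self.vmax <= 0:
            raise InvalidArgumentError("f0, l0 and vmax must be > 0")
        if self.T_rise <= 0 or self.T_fall <= 0 or self.T_e <= 0:
            raise InvalidArgumentError("time constants must be > 0")


@dataclass
class MaxForceTrajectory:
    """Maximum achievable force per muscle per sample, plus cycle maxima."""

    forces: np.ndarray            # (n_samples, n_muscles) N
    f_max: np.ndarray             # (n_muscles,) cycle maxima N
    muscle_names: tuple[str, ...]

    def __post_init__(self):
        if np.any(self.forces < 0):
            raise InvalidArgumentError("max achievable forces must be >= 0")


def active_force_length(l_norm, p: MuscleParams):
    l_norm = np.asarray(l_norm, dtype=float)
    return np.exp(-(((l_norm - 1.0) / p.fl_width) ** 2))


def force_velocity(v_norm, p: MuscleParams):
    """Force-velocity scaling; ``v_norm`` = fiber velocity / (vmax l0),
    lengthening positive. Zero at v = -1, one at v = 0, saturating to
    ``fv_ecc_max`` for fast lengthening; C1 at v = 0."""
    v = np.asarray(v_norm, dtype=float)
    af = p.fv_shape
    con = np.clip(1.0 + v, 0.0, None) / (1.0 - np.minimum(v, 0.0) / af)
    slope0 = 1.0 + 1.0 / af
    scale = (p.fv_ecc_max - 1.0) / slope0
    ecc = p.fv_ecc_max - (p.fv_ecc_max - 1.0) * np.exp(-np.maximum(v, 0.0) / scale)
    return np.where(v <= 0.0, con, ecc)


def passive_force_length(l_norm, p: MuscleParams):
    l_norm = np.asarray(l_norm, dtype=float)
    k, e0 = p.passive_exponent, p.passive_strain
    raw = (np.exp(k * (l_norm - 1.0) / e0) - 1.0) / (np.exp(k) - 1.0)
    return np.where(l_norm > 1.0, raw, 0.0)


def hill_force(a, l_norm, v_norm, p: MuscleParams,
               include_passive: bool = True):
    """Muscle force (N) of the rigid-tendon Hill model.

    ``force = f0 * (a * fl(l_norm) * fv(v_norm) + fp(l_norm))``; the
    passive term can be excluded for an active-only force.
    """
    a_arr = np.asarray(a, dtype=float)
    l_arr = np.asarray(l_norm, dtype=float)
    if np.any((a_arr < 0) | (a_arr > 1)):
        raise InvalidArgumentError("activation must lie in [0, 1]")
    if np.any(l_arr <= 0):
        raise InvalidArgumentError("normalized length must be > 0")
    active = a_arr * active_force_length(l_arr, p) * force_velocity(v_norm, p)
    passive = passive_force_length(l_arr, p) if include_passive else 0.0
    return p.f0 * (active + passive)


def max_achievable_forces(trial: GaitTrial, params: list[MuscleParams],
                          include_passive: bool = True) -> MaxForceTrajectory:
    """Step 1 of the physiological static optimization.

    Evaluates the Hill relation at full activation (a = 1) on the
    trial's fiber kinematics for every muscle in ``params`` and records
    the per-muscle cycle maximum.
    """
    names = [p.name for p in params]
    missing = [n for n in names if n not in trial.muscle_names]
    if missing:
        raise SchemaError(f"muscle(s) not present in trial: {missing}")
    idx = [trial.muscle_names.index(n) for n in names]
    n = trial.n_samples
    forces = np.zeros((n, len(params)))
    v_m = trial.contraction_velocities()  # shortening positive
    for col, (p, i) in enumerate(zip(params, idx)):
        l_norm = trial.muscle_lengths[:, i] / p.l0
        # fiber velocity normalized to vmax*l0, lengthening positive
        v_norm = -v_m[:, i] / (p.vmax * p.l0)
        forces[:, col] = hill_force(1.0, l_norm, v_norm, p,
                                    include_passive=include_passive)
    return MaxForceTrajectory(forces=forces, f_max=forces.max(axis=0),
                              muscle_names=tuple(names))


def activation_rate_constants(p: MuscleParams, convention: str = "literal"):
    """(t1, t2) of the first-order activation ODE
    ``da/dt = (u - a)(t1 u + t2)``.

    ``t2 = 1/T_fall`` always. The default "literal" convention computes
    ``t1 = 1/(T_rise - t2)``; the "standard" convention uses
    ``t1 = 1/T_rise - t2`` (rate 1/T_rise at full excitation, 1/T_fall
    at rest).
    """
    t2 = 1.0 / p.T_fall
    if convention == "literal":
        if abs(p.T_rise - t2) < 1e-12:
            raise InvalidArgumentError(
                "literal convention requires T_rise != 1/T_fall")
        t1 = 1.0 / (p.T_rise - t2)
    elif convention == "standard":
        t1 = 1.0 / p.T_rise - t2
    else:
        raise InvalidArgumentError(f"unknown convention: {convention!r}")
    return t1, t2


def simulate_activation(u, p: MuscleParams, a0: float = 0.0,
                        dt: float = 0.01,
                        convention: str = "literal") -> np.ndarray:
    """Integrate the physiological activation ODE for an excitation series.

    The input is held piecewise-constant over each step, for which the
    ODE is linear with constant coefficients; each step therefore uses
    the exact exponential update ``a <- u + (a - u) exp(-(t1 u + t2) dt)``
    (no truncation error beyond the input hold). Output is clipped-free:
    it stays in [0, 1] because every update is a convex combination.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise InvalidArgumentError("excitation must lie in [0, 1]")
    if dt <= 0:
        raise InvalidArgumentError("dt must be > 0")
    if not 0.0 <= a0 <= 1.0:
        raise InvalidArgumentError("a0 must lie in [0, 1]")
    t1, t2 = activation_rate_constants(p, convention)
    rates = t1 * u + t2
    if np.any(rates <= 0):
        raise InvalidArgumentError(
            "nonpositive activation rate t1*u + t2; adjust time constants "
            "or use the 'standard' convention")
    a = np.empty_like(u)
    a[0] = a0
    decay = np.exp(-rates * dt)
    for i in range(1, len(u)):
        a[i] = u[i - 1] + (a[i - 1] - u[i - 1]) * decay[i - 1]
    return a
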