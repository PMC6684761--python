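"""Per-timestep distribution of net joint torques between muscles and motors.

This is the second step of the physiological static optimization: given
the net joint torque vector ``T`` and the maximally achievable muscle
forces ``F*`` at one instant, find muscle activations ``a`` in [0, 1]
and orthosis torques ``To`` within actuator bounds such that

    R . [a * F*, To] = T

while minimizing one of four physiological cost functions:

* CF1 — squared muscle forces normalized to the isometric force f0 plus
  squared motor torques normalized to To_max;
* CF2 — squared muscle and motor powers;
* CF3 — as CF1 but normalizing each muscle by the cycle maximum f_max of
  its achievable-force trajectory;
* CF4 — minimax: the largest normalized muscle-force or motor-torque
  term, solved through an epigraph reformulation.

The orthosis columns of ``R`` are unit vectors (moment arm 1 at the
actuated joint), so the equality constraint is linear in the decision
variables and motors can always restore it exactly when within bounds.

An "assistance" constraint keeps the two actuators from fighting each
other. The default interprets it per joint as sign agreement between the
FES torque and the motor torque; a strict-literal mode multiplying the
two cost components is available for comparison, along with "off".

Fatigue enters through the per-muscle capacity scale ``psi``: it scales
the available muscle force in the constraint (capacity coupling) and
weights the muscle cost terms (cost coupling); both couplings are
individually switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import ConfigurationError, InfeasibleError, InvalidArgumentError
from .gait_model import GaitTrial
from .muscle_model import MaxForceTrajectory, MuscleParams

COST_IDS = ("CF1", "CF2", "CF3", "CF4")

_TIE_WEIGHT = 1e-9  # secondary lexicographic preference for small ||To||


# ---------------------------------------------------------------------------
# Problem and solution containers
# ---------------------------------------------------------------------------

@dataclass
class LoadSharingProblem:
    """One instant of the torque-distribution problem.

    ``R`` is the signed moment-arm matrix over [muscles | motors]; its
    motor block must be the identity. ``psi`` holds per-muscle fatigue
    capacity scales in (0, 1] (defaults to ones = unfatigued).
    """

    R: np.ndarray                 # (3, n_m + 3)
    T: np.ndarray                 # (3,)
    f_star: np.ndarray            # (n_m,) unfatigued max achievable force
    f0: np.ndarray                # (n_m,)
    f_max: np.ndarray             # (n_m,)
    To_max: np.ndarray            # (3,)
    To_min: np.ndarray            # (3,)
    delta: float = 0.5
    n: int = 2
    cost_id: str = "CF1"
    v_m: np.ndarray | None = None     # (n_m,) contraction velocities (CF2)
    omega: np.ndarray | None = None   # (3,) joint angular velocities (CF2)
    psi: np.ndarray | None = None
    assistance: str = "sign_agreement"
    fatigue_in_cost: bool = True
    fatigue_in_capacity: bool = True

    def __post_init__(self):
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        self.T = np.asarray(self.T, dtype=float)
        for name in ("f_star", "f0", "f_max", "To_max", "To_min"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n_j = self.R.shape[0]
        n_m = self.R.shape[1] - n_j
        if n_m < 0 or self.T.shape != (n_j,):
            raise InvalidArgumentError("inconsistent R / T dimensions")
        for name in ("f_star", "f0", "f_max"):
            if getattr(self, name).shape != (n_m,):
                raise InvalidArgumentError(f"{name} must have shape ({n_m},)")
        for name in ("To_max", "To_min"):
            if getattr(self, name).shape != (n_j,):
                raise InvalidArgumentError(f"{name} must have shape ({n_j},)")
        if np.any(self.To_min > 0) or np.any(self.To_max < 0):
            raise InvalidArgumentError("need To_min <= 0 <= To_max")
        if not 0.0 <= self.delta <= 1.0:
            raise InvalidArgumentError("delta must lie in [0, 1]")
        if self.cost_id not in COST_IDS:
            raise InvalidArgumentError(f"unknown cost_id: {self.cost_id!r}")
        if self.assistance not in ("sign_agreement", "literal", "off"):
            raise InvalidArgumentError(f"unknown assistance mode: {self.assistance!r}")
        if not np.allclose(self.R[:, n_m:], np.eye(n_j)):
            raise InvalidArgumentError("motor columns of R must be unit vectors")
        if self.psi is None:
            self.psi = np.ones(n_m)
        else:
            self.psi = np.asarray(self.psi, dtype=float)
            if self.psi.shape != (n_m,) or np.any(self.psi <= 0) or np.any(self.psi > 1):
                raise InvalidArgumentError("psi must have shape (n_m,) in (0, 1]")
        if self.v_m is not None:
            self.v_m = np.asarray(self.v_m, dtype=float)
        if self.omega is not None:
            self.omega = np.asarray(self.omega, dtype=float)

    @property
    def n_joints(self) -> int:
        return self.R.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.R.shape[1] - self.R.shape[0]

    @property
    def psi_capacity(self) -> np.ndarray:
        return self.psi if self.fatigue_in_capacity else np.ones(self.n_muscles)

    @property
    def psi_cost(self) -> np.ndarray:
        return self.psi if self.fatigue_in_cost else np.ones(self.n_muscles)

    @property
    def muscle_torque_matrix(self) -> np.ndarray:
        """(n_j, n_m) map from activations to FES joint torques,
        including the fatigue capacity scale."""
        return self.R[:, :self.n_muscles] * (self.psi_capacity * self.f_star)

    def muscle_forces(self, a) -> np.ndarray:
        return np.asarray(a, dtype=float) * self.psi_capacity * self.f_star

    def fes_torques(self, a) -> np.ndarray:
        return self.muscle_torque_matrix @ np.asarray(a, dtype=float)


@dataclass
class LoadSharingResult:
    a: np.ndarray
    To: np.ndarray
    objective: float
    status: str
    residual: float


@dataclass
class ActuationSolution:
    """Trajectory of activations, orthosis torques and torque shares."""

    time: np.ndarray                 # (n,)
    activations: np.ndarray          # (n, n_m)
    orthosis_torques: np.ndarray     # (n, 3)
    muscle_forces: np.ndarray        # (n, n_m)
    fes_torques: np.ndarray          # (n, 3)
    net_torques: np.ndarray          # (n, 3)
    objectives: np.ndarray           # (n,)
    residuals: np.ndarray            # (n,)
    statuses: list[str]
    muscle_names: tuple[str, ...]

    def validate(self, tol_factor: float = 1e-6) -> None:
        tol = tol_factor * max(1.0, float(np.max(np.abs(self.net_torques))))
        worst = float(np.max(self.residuals))
        if worst > tol:
            raise InfeasibleError(
                f"torque balance residual {worst:.3e} exceeds {tol:.3e}",
                gap=worst)
        if np.any((self.activations < -1e-9) | (self.activations > 1 + 1e-9)):
            raise InvalidArgumentError("activations out of [0, 1]")

    def write(self, directory, prefix: str = "solution") -> None:
        """Write the per-sample CSV plus a JSON metadata sidecar."""
        import hashlib
        import json
        import os

        import pandas as pd

        os.makedirs(directory, exist_ok=True)
        cols = {"time": self.time}
        for i, m in enumerate(self.muscle_names):
            cols[f"a_{m}"] = self.activations[:, i]
        for k, j in enumerate(("hip", "knee", "ankle")):
            cols[f"To_{j}"] = self.orthosis_torques[:, k]
        for k, j in enumerate(("hip", "knee", "ankle")):
            cols[f"Tfes_{j}"] = self.fes_torques[:, k]
        for k, j in enumerate(("hip", "knee", "ankle")):
            cols[f"T_{j}"] = self.net_torques[:, k]
        cols["objective"] = self.objectives
        cols["residual"] = self.residuals
        cols["status"] = self.statuses
        df = pd.DataFrame(cols)
        csv_path = os.path.join(directory, f"{prefix}.csv")
        df.to_csv(csv_path, index=False, float_format="%.17g")
        with open(csv_path, "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        meta = {
            "n_samples": int(len(self.time)),
            "residual_max": float(np.max(self.residuals)),
            "residual_mean": float(np.mean(self.residuals)),
            "objective_mean": float(np.mean(self.objectives)),
            "csv_sha256": digest,
            "statuses": sorted(set(self.statuses)),
        }
        with open(os.path.join(directory, f"{prefix}_meta.json"), "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


@dataclass(frozen=True)
class LoadSharingOptions:
    """Solver and model options for trajectory solves."""

    cost_id: str = "CF1"
    delta: float = 0.5
    n: int = 2
    To_max: tuple[float, float, float] = (40.0, 40.0, 40.0)
    To_min: tuple[float, float, float] | None = None  # default -To_max
    assistance: str = "sign_agreement"
    n_starts: int = 3
    tol_factor: float = 1e-6   # residual tolerance, x max(1, ||T||_inf)
    maxiter: int = 300

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        hi = np.asarray(self.To_max, dtype=float)
        lo = (np.asarray(self.To_min, dtype=float)
              if self.To_min is not None else -hi)
        return lo, hi


# ---------------------------------------------------------------------------
# Cost evaluation
# ---------------------------------------------------------------------------

def _normalizers(problem: LoadSharingProblem):
    if problem.cost_id in ("CF1",):
        norm = problem.f0
    elif problem.cost_id in ("CF3", "CF4"):
        norm = problem.f_max
    else:
        norm = None
    if norm is not None and np.any(norm == 0):
        raise ConfigurationError(
            f"zero muscle-force normalizer for {problem.cost_id}")
    # a zero To_max is only a configuration error if the motor can move;
    # a locked motor (zero-width bound) contributes no cost term
    movable = (problem.To_max - problem.To_min) > 0
    if problem.cost_id != "CF2" and np.any(movable & (problem.To_max == 0)):
        raise ConfigurationError("zero To_max normalizer for a movable motor")
    return norm


def _motor_scale(problem: LoadSharingProblem) -> np.ndarray:
    """To_max with locked joints replaced by 1 (their torque is pinned,
    so the substitute scale never sees a nonzero numerator)."""
    return np.where(problem.To_max > 0, problem.To_max, 1.0)


def _muscle_terms(problem: LoadSharingProblem, a: np.ndarray) -> np.ndarray:
    """Signed base of each (pre-exponent) muscle cost term."""
    cid = problem.cost_id
    if cid in ("CF1", "CF3", "CF4"):
        return a * problem.f_star / _normalizers(problem)
    if cid == "CF2":
        if problem.v_m is None:
            raise ConfigurationError("CF2 requires contraction velocities v_m")
        return -a * problem.f_star * problem.v_m
    raise InvalidArgumentError(f"unknown cost_id: {cid!r}")


def _motor_terms(problem: LoadSharingProblem, To: np.ndarray) -> np.ndarray:
    cid = problem.cost_id
    if cid in ("CF1", "CF3", "CF4"):
        _normalizers(problem)
        return To / _motor_scale(problem)
    if cid == "CF2":
        if problem.omega is None:
            raise ConfigurationError("CF2 requires joint velocities omega")
        return To * problem.omega
    raise InvalidArgumentError(f"unknown cost_id: {cid!r}")


def muscle_cost(problem: LoadSharingProblem, a) -> float:
    """J(A): the weighted muscle part of the cost."""
    a = np.asarray(a, dtype=float)
    base = _muscle_terms(problem, a)
    if problem.cost_id == "CF4":
        raise InvalidArgumentError("CF4 has no additive muscle part")
    return float(problem.delta
                 * np.sum(problem.psi_cost * base ** problem.n))


def motor_cost(problem: LoadSharingProblem, To) -> float:
    """H(To): the weighted electromechanical part of the cost."""
    base = _motor_terms(problem, np.asarray(To, dtype=float))
    if problem.cost_id == "CF4":
        raise InvalidArgumentError("CF4 has no additive motor part")
    return float((1.0 - problem.delta) * np.sum(base ** problem.n))


def evaluate_cost(problem: LoadSharingProblem, a, To) -> float:
    """Cost of a candidate (a, To) under the problem's cost function."""
    a = np.asarray(a, dtype=float)
    To = np.asarray(To, dtype=float)
    if a.shape != (problem.n_muscles,) or To.shape != (problem.n_joints,):
        raise InvalidArgumentError("a / To dimensioned inconsistently")
    if problem.cost_id == "CF4":
        terms = np.concatenate([
            problem.psi_cost * _muscle_terms(problem, a),
            _motor_terms(problem, To),
        ])
        return float(np.max(terms))
    return muscle_cost(problem, a) + motor_cost(problem, To)


# ---------------------------------------------------------------------------
# Single-timestep solver
# ---------------------------------------------------------------------------

def _feasibility_gap(problem: LoadSharingProblem, lo, hi) -> float:
    """Smallest achievable ||A_eq x - T||_inf over the box (linear program)."""
    n_m, n_j = problem.n_muscles, problem.n_joints
    A = np.hstack([problem.muscle_torque_matrix, np.eye(n_j)])
    n_x = n_m + n_j
    c = np.zeros(n_x + 1)
    c[-1] = 1.0
    ones = np.ones((n_j, 1))
    A_ub = np.vstack([np.hstack([A, -ones]), np.hstack([-A, -ones])])
    b_ub = np.concatenate([problem.T, -problem.T])
    bounds = [(0.0, 1.0)] * n_m + list(zip(lo, hi)) + [(0.0, None)]
    res = optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds,
                           method="highs")
    if not res.success:
        return float("inf")
    return float(res.fun)


def _objective_with_grad(problem: LoadSharingProblem):
    """(fun, grad) closures over x = [a, To] for the additive costs."""
    n_m, n_j = problem.n_muscles, problem.n_joints
    n_pow = int(problem.n)
    delta = problem.delta
    w = problem.psi_cost
    to_scale = np.where(problem.To_max != 0, problem.To_max, 1.0)

    if problem.cost_id in ("CF1", "CF3"):
        norm = _normalizers(problem)
        mus_lin = problem.f_star / norm          # term = mus_lin * a
        mot_lin = 1.0 / _motor_scale(problem)
        mot_mul = None
    elif problem.cost_id == "CF2":
        if problem.v_m is None or problem.omega is None:
            raise ConfigurationError("CF2 requires v_m and omega")
        mus_lin = -problem.f_star * problem.v_m
        mot_lin = None
        mot_mul = problem.omega
    else:
        raise InvalidArgumentError(problem.cost_id)

    def fun(x):
        a, To = x[:n_m], x[n_m:n_m + n_j]
        mus = mus_lin * a
        mot = mot_lin * To if mot_lin is not None else mot_mul * To
        tie = _TIE_WEIGHT * np.sum((To / to_scale) ** 2)
        return (delta * np.sum(w * mus ** n_pow)
                + (1 - delta) * np.sum(mot ** n_pow) + tie)

    def grad(x):
        a, To = x[:n_m], x[n_m:n_m + n_j]
        mus = mus_lin * a
        mot = mot_lin * To if mot_lin is not None else mot_mul * To
        g = np.zeros_like(x)
        g[:n_m] = delta * w * n_pow * mus ** (n_pow - 1) * mus_lin
        mot_slope = mot_lin if mot_lin is not None else mot_mul
        g[n_m:n_m + n_j] = ((1 - delta) * n_pow * mot ** (n_pow - 1) * mot_slope
                            + _TIE_WEIGHT * 2.0 * To / to_scale ** 2)
        return g

    return fun, grad


def _assistance_constraints(problem: LoadSharingProblem, n_x: int):
    """Inequality constraints (>= 0) implementing the assistance rule."""
    n_m, n_j = problem.n_muscles, problem.n_joints
    A_m = problem.muscle_torque_matrix
    cons = []
    if problem.assistance == "sign_agreement":
        for k in range(n_j):
            row = A_m[k]

            def fun(x, row=row, k=k):
                return float((row @ x[:n_m]) * x[n_m + k])

            def jac(x, row=row, k=k):
                g = np.zeros(n_x)
                g[:n_m] = row * x[n_m + k]
                g[n_m + k] = row @ x[:n_m]
                return g

            cons.append({"type": "ineq", "fun": fun, "jac": jac})
    elif problem.assistance == "literal":
        # J(A) * H(To) <= 0 taken at face value: for the nonnegative
        # additive costs this forces one component to zero.
        sub = replace(problem, assistance="off") if problem.cost_id != "CF4" \
            else None
        if sub is None:
            raise ConfigurationError("literal assistance undefined for CF4")

        def fun(x):
            return -muscle_cost(sub, x[:n_m]) * motor_cost(sub, x[n_m:n_m + sub.n_joints])

        cons.append({"type": "ineq", "fun": fun})
    return cons


def solve_timestep(problem: LoadSharingProblem,
                   warm_start: np.ndarray | None = None,
                   n_starts: int = 3,
                   tol_factor: float = 1e-6,
                   maxiter: int = 300) -> LoadSharingResult:
    """Solve one instant of the load-sharing problem.

    Runs an SQP solver from up to ``n_starts`` deterministic starting
    points (all-zeros, the warm start if given, and the box midpoint)
    and returns the best solution whose torque-balance residual is
    within ``tol_factor * max(1, ||T||_inf)``. CF4 is solved through its
    epigraph reformulation (an added scalar bounding every normalized
    term). Raises :class:`InfeasibleError` when no admissible actuation
    can meet the torque demand, reporting the achievable-torque gap.
    """
    n_m, n_j = problem.n_muscles, problem.n_joints
    lo, hi = problem.To_min, problem.To_max
    tol_res = tol_factor * max(1.0, float(np.max(np.abs(problem.T))))

    # quick feasibility: a = 0, To = T works when T is inside motor bounds
    if not np.all((problem.T >= lo - 1e-12) & (problem.T <= hi + 1e-12)):
        gap = _feasibility_gap(problem, lo, hi)
        if gap > max(tol_res, 1e-9):
            raise InfeasibleError(
                f"torque demand unreachable within bounds "
                f"(achievable-torque gap {gap:.4g} N.m)", gap=gap)

    A_m = problem.muscle_torque_matrix
    epigraph = problem.cost_id == "CF4"
    n_x = n_m + n_j + (1 if epigraph else 0)

    A_eq = np.zeros((n_j, n_x))
    A_eq[:, :n_m] = A_m
    A_eq[:, n_m:n_m + n_j] = np.eye(n_j)
    eq = {"type": "eq",
          "fun": lambda x: A_eq @ x - problem.T,
          "jac": lambda x: A_eq}

    cons = [eq] + _assistance_constraints(problem, n_x)

    if epigraph:
        to_scale = np.where(problem.To_max != 0, problem.To_max, 1.0)
        mus_lin = problem.psi_cost * problem.f_star / _normalizers(problem)
        G = np.zeros((n_m + n_j, n_x))
        G[:n_m, :n_m] = -np.diag(mus_lin)
        G[n_m:, n_m:n_m + n_j] = -np.diag(1.0 / _motor_scale(problem))
        G[:, -1] = 1.0
        cons.append({"type": "ineq",
                     "fun": lambda x: G @ x,
                     "jac": lambda x: G})

        def fun(x):
            To = x[n_m:n_m + n_j]
            return x[-1] + _TIE_WEIGHT * np.sum((To / to_scale) ** 2)

        def grad(x):
            g = np.zeros(n_x)
            g[-1] = 1.0
            To = x[n_m:n_m + n_j]
            g[n_m:n_m + n_j] = _TIE_WEIGHT * 2.0 * To / to_scale ** 2
            return g
    else:
        fun, grad = _objective_with_grad(problem)

    def pad(a0, To0):
        x0 = np.concatenate([a0, To0])
        if epigraph:
            s0 = max(float(np.max(G[:, :-1] @ x0 * -1.0)), 0.0) + 1e-3
            x0 = np.append(x0, s0)
        return x0

    starts = [pad(np.zeros(n_m), np.clip(problem.T, lo, hi))]
    if warm_start is not None and warm_start.shape == (n_m + n_j,):
        starts.append(pad(warm_start[:n_m], warm_start[n_m:]))
    starts.append(pad(np.full(n_m, 0.5), np.zeros(n_j)))
    starts = starts[:max(1, n_starts)]

    bounds = ([(0.0, 1.0)] * n_m + list(zip(lo, hi))
              + ([(None, None)] if epigraph else []))

    best = None
    for x0 in starts:
        res = optimize.minimize(fun, x0, jac=grad, bounds=bounds,
                                constraints=cons, method="SLSQP",
                                options={"maxiter": maxiter, "ftol": 1e-12})
        x = res.x
        a = np.clip(x[:n_m], 0.0, 1.0)
        # motors restore the (linear) equality exactly when in bounds
        To = np.clip(problem.T - A_m @ a, lo, hi)
        resid = float(np.max(np.abs(A_m @ a + To - problem.T)))
        try:
            obj = evaluate_cost(problem, a, To)
        except ConfigurationError:
            raise
        ok = resid <= tol_res
        key = (not ok, obj + _TIE_WEIGHT * float(np.sum(To ** 2)), resid)
        if best is None or key < best[0]:
            status = "converged" if (res.success and ok) else (
                "residual_exceeded" if not ok else "solver_warning")
            best = (key, LoadSharingResult(a=a, To=To, objective=obj,
                                           status=status, residual=resid))
    return best[1]


def solve_trajectory(trial: GaitTrial, maxforce: MaxForceTrajectory,
                     options: LoadSharingOptions = LoadSharingOptions(),
                     params: Sequence[MuscleParams] | None = None,
                     psi: np.ndarray | None = None) -> ActuationSolution:
    """Solve the load-sharing problem at every sample of a trial.

    Consecutive samples are warm-started from the previous solution. The
    hip, knee and ankle are solved simultaneously, which is what couples
    the biarticular muscles correctly. ``psi`` optionally supplies the
    per-muscle fatigue capacity scale, held constant over the cycle.

    Raises :class:`InfeasibleError` at the end listing every infeasible
    sample and its achievable-torque gap.
    """
    if params is None:
        from .muscles import default_muscle_params
        params = default_muscle_params()
    names = tuple(p.name for p in params)
    if names != maxforce.muscle_names:
        raise InvalidArgumentError("params and maxforce muscle sets differ")
    idx = [trial.muscle_names.index(n) for n in names]
    f0 = np.array([p.f0 for p in params])
    lo, hi = options.bounds()
    n = trial.n_samples
    n_m = len(params)
    v_all = trial.contraction_velocities()

    a_out = np.zeros((n, n_m))
    To_out = np.zeros((n, 3))
    obj_out = np.zeros(n)
    res_out = np.zeros(n)
    statuses: list[str] = []
    warm = None
    failures: list[tuple[int, float]] = []
    problem = None
    for s in range(n):
        R = np.hstack([trial.moment_arms[s][:, idx], np.eye(3)])
        problem = LoadSharingProblem(
            R=R, T=trial.net_torques[s], f_star=maxforce.forces[s],
            f0=f0, f_max=maxforce.f_max, To_max=hi, To_min=lo,
            delta=options.delta, n=options.n, cost_id=options.cost_id,
            v_m=v_all[s][idx], omega=trial.joint_velocities[s],
            psi=psi, assistance=options.assistance)
        try:
            r = solve_timestep(problem, warm_start=warm,
                               n_starts=options.n_starts,
                               tol_factor=options.tol_factor,
                               maxiter=options.maxiter)
        except InfeasibleError as exc:
            failures.append((s, exc.gap if exc.gap is not None else float("nan")))
            statuses.append("infeasible")
            continue
        a_out[s] = r.a
        To_out[s] = r.To
        obj_out[s] = r.objective
        res_out[s] = r.residual
        statuses.append(r.status)
        warm = np.concatenate([r.a, r.To])
    if failures:
        raise InfeasibleError(
            "infeasible sample(s) (index, gap N.m): "
            + ", ".join(f"({i}, {g:.4g})" for i, g in failures),
            samples=[i for i, _ in failures])

    psi_cap = problem.psi_capacity if psi is not None else np.ones(n_m)
    forces = a_out * (psi_cap * maxforce.forces)
    fes = np.einsum("sjm,sm->sj", trial.moment_arms[:, :, idx], forces)
    return ActuationSolution(
        time=trial.time, activations=a_out, orthosis_torques=To_out,
        muscle_forces=forces, fes_torques=fes,
        net_torques=trial.net_torques, objectives=obj_out,
        residuals=res_out, statuses=statuses, muscle_names=names)


# ---------------------------------------------------------------------------
# Exhaustive grid oracle (for small instances)
# ---------------------------------------------------------------------------

def brute_force_oracle(problem: LoadSharingProblem,
                       grid_resolution: float = 1e-3):
    """Exhaustive grid minimum of a small load-sharing instance.

    Grids the muscle activations only (at most 3 muscles); the motor
    torques are eliminated through the linear torque equality. A joint
    whose motor is locked (zero-width bound) accepts grid points whose
    residual is below the grid's Lipschitz bound. Honors the activation
    box, motor bounds and the sign-agreement assistance constraint, and
    applies the same minimal-``||To||`` tie-break as the solver.
    """
    n_m, n_j = problem.n_muscles, problem.n_joints
    if n_m > 3:
        raise InvalidArgumentError("oracle limited to <= 3 muscle variables")
    A_m = problem.muscle_torque_matrix
    lo, hi = problem.To_min, problem.To_max
    locked = (hi - lo) == 0.0
    # per-locked-joint residual tolerance: grid step x row Lipschitz constant
    lip = np.sum(np.abs(A_m), axis=1)
    lock_tol = np.maximum(grid_resolution * lip, 1e-12)

    axes = [np.linspace(0.0, 1.0, int(round(1.0 / grid_resolution)) + 1)
            for _ in range(n_m)]
    grids = np.meshgrid(*axes, indexing="ij")
    A = np.stack([g.ravel() for g in grids], axis=-1)   # (N, n_m)
    Tfes = A @ A_m.T                                    # (N, n_j)
    To = problem.T - Tfes
    feas = np.ones(len(A), dtype=bool)
    for k in range(n_j):
        if locked[k]:
            feas &= np.abs(To[:, k] - lo[k]) <= lock_tol[k]
        else:
            feas &= (To[:, k] >= lo[k] - 1e-12) & (To[:, k] <= hi[k] + 1e-12)
    To = np.where(locked, lo, To)
    if problem.assistance == "sign_agreement":
        feas &= np.all(Tfes * To >= -1e-12, axis=1)
    if not np.any(feas):
        raise InfeasibleError("empty feasible set on the oracle grid")
    idx = np.flatnonzero(feas)
    objs = _vectorized_cost(problem, A[idx], To[idx])
    ties = objs + _TIE_WEIGHT * np.sum(To[idx] ** 2, axis=1)
    best = idx[int(np.argmin(ties))]
    return A[best], To[best], float(evaluate_cost(problem, A[best], To[best]))


def _vectorized_cost(problem: LoadSharingProblem, A: np.ndarray,
                     To: np.ndarray) -> np.ndarray:
    """Cost of many (a, To) candidates at once (rows of A and To)."""
    cid = problem.cost_id
    w = problem.psi_cost
    if cid in ("CF1", "CF3", "CF4"):
        mus = A * (problem.f_star / _normalizers(problem))
        mot = To / _motor_scale(problem)
    else:
        mus = -A * (problem.f_star * problem.v_m)
        mot = To * problem.omega
    if cid == "CF4":
        return np.max(np.hstack([w * mus, mot]), axis=1)
    return (problem.delta * np.sum(w * mus ** problem.n, axis=1)
            + (1 - problem.delta) * np.sum(mot ** problem.n, axis=1))
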