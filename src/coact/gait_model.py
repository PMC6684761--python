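"""Gait inputs: synthetic normative gait, planar inverse dynamics, trial I/O.

The torque-distribution method downstream only needs a *consistent* gait
trial: joint kinematics, net joint torques that follow from those
kinematics through a rigid-body model, and muscle-tendon lengths /
velocities / moment arms that follow from the joint angles through a
geometric model. This module provides all three for a single leg.

Conventions
-----------
* Hip flexion, knee flexion and ankle dorsiflexion are positive.
* A muscle's moment arm is signed so that (moment arm x muscle force)
  adds torque of the muscle's anatomical action.
* Units are strictly SI in memory; degrees are accepted only at the file
  boundary via an explicit header flag.
* Sampling follows the percent-of-gait-cycle convention: 101 samples per
  cycle by default, sample 0 at t = 0.

The synthetic trial models the leg as a suspended (swing-style) planar
three-link chain — thigh, shank, foot — driven through smooth periodic
joint trajectories; ground contact is deliberately not modelled.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, InvalidArgumentError, SchemaError
from .muscles import ACTIONS, JOINTS, MUSCLES, NOMINAL_MOMENT_ARMS, spanned_joints

_DEG = np.pi / 180.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """One rigid segment of the planar chain."""

    mass: float           # kg
    length: float         # m, proximal joint to distal joint (or toe)
    com: float            # m, proximal joint to centre of mass
    inertia: float        # kg m^2 about the centre of mass

    def __post_init__(self):
        if min(self.mass, self.length, self.com, self.inertia) <= 0:
            raise InvalidArgumentError(
                "segment mass, length, com distance and inertia must be > 0")


@dataclass(frozen=True)
class PlanarSegmentModel:
    """Thigh/shank/foot inertial parameters plus gravity and subject mass."""

    thigh: Segment
    shank: Segment
    foot: Segment
    gravity: float = 9.81      # m/s^2
    subject_mass: float = 72.6  # kg

    @property
    def segments(self) -> tuple[Segment, Segment, Segment]:
        return (self.thigh, self.shank, self.foot)

    @classmethod
    def default_adult(cls, total_mass: float = 72.6,
                      height: float = 1.70) -> "PlanarSegmentModel":
        """Anthropometric defaults (segment mass/length fractions of a
        standard adult regression table) scaled to subject mass/height."""
        def seg(mf, lf, cf, kf):
            length = lf * height
            mass = mf * total_mass
            com = cf * length
            gyr = kf * length
            return Segment(mass=mass, length=length, com=com,
                           inertia=mass * gyr ** 2)

        return cls(
            thigh=seg(0.1416, 0.245, 0.41, 0.33),
            shank=seg(0.0433, 0.246, 0.44, 0.30),
            foot=seg(0.0137, 0.152, 0.44, 0.26),
            subject_mass=total_mass,
        )


@dataclass(frozen=True)
class MuscleGeometry:
    """Moment arms as polynomials in joint angle, plus reference lengths.

    ``moment_arm_coeffs[muscle][joint]`` holds ascending polynomial
    coefficients in the joint angle (radians); the constant term is the
    signed nominal moment arm. ``reference_lengths[muscle]`` is the fiber
    length at the neutral posture (all joint angles zero).
    """

    reference_lengths: dict[str, float]
    moment_arm_coeffs: dict[str, dict[str, np.ndarray]]

    def __post_init__(self):
        for m, per_joint in self.moment_arm_coeffs.items():
            span = set(spanned_joints(m))
            if set(per_joint) != span:
                raise SchemaError(
                    f"{m}: moment-arm joints {sorted(per_joint)} do not match "
                    f"spanned joints {sorted(span)}")
            for j, c in per_joint.items():
                if abs(np.asarray(c, dtype=float)[0]) <= 0:
                    raise SchemaError(
                        f"{m}/{j}: constant moment-arm term must be nonzero")

    @classmethod
    def default(cls) -> "MuscleGeometry":
        """Constant moment arms at nominal anatomical magnitudes, signed by
        anatomical action; reference fiber length = optimal fiber length."""
        from .muscles import _DEFAULT_F0_L0

        coeffs = {
            m: {
                j: np.array([ACTIONS[m][j] * NOMINAL_MOMENT_ARMS[m][j]])
                for j in spanned_joints(m)
            }
            for m in MUSCLES
        }
        refs = {m: _DEFAULT_F0_L0[m][1] for m in MUSCLES}
        return cls(reference_lengths=refs, moment_arm_coeffs=coeffs)

    def moment_arm(self, muscle: str, joint: str, angle) -> np.ndarray:
        """Signed moment arm (m) of ``muscle`` about ``joint`` at ``angle``."""
        c = self.moment_arm_coeffs[muscle].get(joint)
        if c is None:
            return np.zeros_like(np.asarray(angle, dtype=float))
        return np.polynomial.polynomial.polyval(np.asarray(angle, float), c)

    def length_change(self, muscle: str, joint: str, angle) -> np.ndarray:
        """Muscle-length change due to ``joint`` moving from 0 to ``angle``.

        Equals minus the angle-integral of the moment-arm polynomial, so a
        positive moment arm and positive excursion shorten the muscle.
        """
        c = self.moment_arm_coeffs[muscle].get(joint)
        if c is None:
            return np.zeros_like(np.asarray(angle, dtype=float))
        integ = np.polynomial.polynomial.polyint(c)
        return -np.polynomial.polynomial.polyval(np.asarray(angle, float), integ)


@dataclass
class GaitTrial:
    """One uniformly sampled single-leg gait recording.

    Arrays are indexed ``[sample]`` or ``[sample, joint]`` with joints in
    (hip, knee, ankle) order, and ``[sample, muscle]`` with muscles in
    :data:`coact.muscles.MUSCLES` order. ``moment_arms`` is
    ``[sample, joint, muscle]`` and signed; entries for joints a muscle
    does not span are identically zero.
    """

    time: np.ndarray                  # (n,) s
    joint_angles: np.ndarray          # (n, 3) rad
    joint_velocities: np.ndarray      # (n, 3) rad/s
    joint_accelerations: np.ndarray   # (n, 3) rad/s^2
    net_torques: np.ndarray           # (n, 3) N m
    muscle_lengths: np.ndarray        # (n, m) m
    muscle_velocities: np.ndarray     # (n, m) m/s (lengthening positive)
    moment_arms: np.ndarray           # (n, 3, m) m, signed
    cycle_duration: float             # s
    muscle_names: tuple[str, ...] = MUSCLES

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def contraction_velocities(self) -> np.ndarray:
        """Contraction velocity v = -ldot (shortening positive)."""
        return -self.muscle_velocities

    def validate(self, fd_tol: float = 1e-3) -> None:
        """Check the trial invariants; raise :class:`DataError` on failure.

        ``fd_tol`` bounds the relative mismatch between recorded muscle
        velocities and the central difference of recorded lengths.
        """
        n = self.n_samples
        if n < 2:
            raise DataError("trial needs at least two samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise DataError("time must be strictly increasing")
        if np.any(np.abs(dt - dt[0]) > 1e-9 * max(abs(dt[0]), 1e-300)):
            raise DataError("time step must be constant (1e-9 relative)")
        for k, joint in enumerate(JOINTS):
            for i, m in enumerate(self.muscle_names):
                if joint not in ACTIONS[m] and np.any(self.moment_arms[:, k, i] != 0.0):
                    raise DataError(
                        f"nonzero moment arm of {m} about unspanned joint {joint}")
        # velocities consistent with lengths, interior central differences
        if n >= 3:
            fd = (self.muscle_lengths[2:] - self.muscle_lengths[:-2]) / (2 * dt[0])
            scale = np.maximum(np.max(np.abs(self.muscle_velocities), axis=0), 1e-6)
            err = np.max(np.abs(fd - self.muscle_velocities[1:-1]) / scale)
            # central differences carry an O(dt^2 * l''') discretization term
            bound = max(fd_tol, 10.0 * dt[0] ** 2 / self.cycle_duration ** 2 * 1e3)
            if err > bound:
                raise DataError(
                    f"muscle velocities inconsistent with lengths "
                    f"(relative error {err:.2e} > {bound:.2e})")

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"time": self.time}
        for k, j in enumerate(JOINTS):
            cols[f"q_{j}"] = self.joint_angles[:, k]
        for k, j in enumerate(JOINTS):
            cols[f"qd_{j}"] = self.joint_velocities[:, k]
        for k, j in enumerate(JOINTS):
            cols[f"qdd_{j}"] = self.joint_accelerations[:, k]
        for k, j in enumerate(JOINTS):
            cols[f"T_{j}"] = self.net_torques[:, k]
        for i, m in enumerate(self.muscle_names):
            cols[f"lm_{m}"] = self.muscle_lengths[:, i]
        for i, m in enumerate(self.muscle_names):
            cols[f"vm_{m}"] = self.muscle_velocities[:, i]
        for k, j in enumerate(JOINTS):
            for i, m in enumerate(self.muscle_names):
                cols[f"r_{j}_{m}"] = self.moment_arms[:, k, i]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Synthetic normative gait
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FourierSeries:
    """Truncated Fourier series q(t) = a0 + sum_h ah cos(h w t) + bh sin(h w t)."""

    a0: float
    cos: tuple[float, ...] = ()
    sin: tuple[float, ...] = ()

    def evaluate(self, t: np.ndarray, period: float, derivative: int = 0) -> np.ndarray:
        w = 2.0 * np.pi / period
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.a0 if derivative == 0 else 0.0)
        n_h = max(len(self.cos), len(self.sin))
        for h in range(1, n_h + 1):
            a = self.cos[h - 1] if h <= len(self.cos) else 0.0
            b = self.sin[h - 1] if h <= len(self.sin) else 0.0
            wh = h * w
            ph = wh * t
            if derivative == 0:
                out += a * np.cos(ph) + b * np.sin(ph)
            elif derivative == 1:
                out += wh * (-a * np.sin(ph) + b * np.cos(ph))
            elif derivative == 2:
                out += wh ** 2 * (-a * np.cos(ph) - b * np.sin(ph))
            else:
                raise InvalidArgumentError("derivative order must be 0, 1 or 2")
        return out


#: Default joint-angle series (radians) approximating normative sagittal
#: gait: hip flexion swinging roughly -11..28 deg, a double-bump knee
#: flexion pattern peaking near 60 deg, and a +-9 deg ankle excursion.
DEFAULT_FOURIER: dict[str, FourierSeries] = {
    "hip": FourierSeries(a0=0.15, cos=(0.32,), sin=(0.10,)),
    "knee": FourierSeries(a0=0.50, cos=(-0.25, -0.15), sin=(0.05, 0.08)),
    "ankle": FourierSeries(a0=0.0, cos=(-0.10,), sin=(0.12,)),
}


def generate_normative_gait(segment_model: PlanarSegmentModel,
                            geometry: MuscleGeometry,
                            n_samples: int = 101,
                            cycle_duration: float = 1.1,
                            seed: int = 0,
                            fourier: dict[str, FourierSeries] | None = None,
                            variability: float = 0.0) -> GaitTrial:
    """Generate a synthetic single-leg normative gait cycle.

    Joint angles follow the (documented) truncated Fourier defaults, so
    velocities and accelerations are exact analytic derivatives and the
    cycle is exactly periodic. Muscle lengths are the reference length
    minus the angle-integral of the moment-arm polynomials; net torques
    come from :func:`planar_inverse_dynamics` on the suspended chain.

    ``variability`` optionally scales a seeded random perturbation of the
    harmonic amplitudes (fractional, e.g. 0.02 for 2 %); at the default 0
    the trial is a pure function of the coefficient table and the same
    seed trivially reproduces the same trial.
    """
    if n_samples < 16:
        raise InvalidArgumentError("n_samples must be >= 16")
    if cycle_duration <= 0:
        raise InvalidArgumentError("cycle_duration must be > 0")
    series = dict(fourier if fourier is not None else DEFAULT_FOURIER)
    if variability > 0.0:
        rng = np.random.default_rng(seed)
        jittered = {}
        for j, s in series.items():
            f = 1.0 + variability * rng.uniform(-1.0, 1.0)
            jittered[j] = FourierSeries(a0=s.a0,
                                        cos=tuple(f * c for c in s.cos),
                                        sin=tuple(f * b for b in s.sin))
        series = jittered

    t = np.linspace(0.0, cycle_duration, n_samples)
    q = np.column_stack([series[j].evaluate(t, cycle_duration, 0) for j in JOINTS])
    qd = np.column_stack([series[j].evaluate(t, cycle_duration, 1) for j in JOINTS])
    qdd = np.column_stack([series[j].evaluate(t, cycle_duration, 2) for j in JOINTS])

    torques = planar_inverse_dynamics(q, qd, qdd, segment_model)

    n_m = len(MUSCLES)
    lm = np.zeros((n_samples, n_m))
    vm = np.zeros((n_samples, n_m))
    arms = np.zeros((n_samples, len(JOINTS), n_m))
    for i, m in enumerate(MUSCLES):
        lm[:, i] = geometry.reference_lengths[m]
        for k, j in enumerate(JOINTS):
            if j in ACTIONS[m]:
                lm[:, i] += geometry.length_change(m, j, q[:, k])
                r = geometry.moment_arm(m, j, q[:, k])
                arms[:, k, i] = r
                vm[:, i] += -r * qd[:, k]

    trial = GaitTrial(time=t, joint_angles=q, joint_velocities=qd,
                      joint_accelerations=qdd, net_torques=torques,
                      muscle_lengths=lm, muscle_velocities=vm,
                      moment_arms=arms, cycle_duration=cycle_duration)
    trial.validate()
    return trial


# ---------------------------------------------------------------------------
# Planar inverse dynamics (suspended three-link chain)
# ---------------------------------------------------------------------------

# Absolute segment angles (CCW from the downward vertical, leg hanging):
#   theta_thigh = q_hip
#   theta_shank = q_hip - q_knee
#   theta_foot  = q_hip - q_knee + q_ankle + pi/2   (foot forward at neutral)
_JOINT_SIGNS = np.array([1.0, -1.0, 1.0])
_THETA_OFFSET = np.array([0.0, 0.0, np.pi / 2.0])
# lower-triangular map q -> theta (theta_i accumulates signs of joints <= i)
_Q_TO_THETA = np.array([[1.0, 0.0, 0.0],
                        [1.0, -1.0, 0.0],
                        [1.0, -1.0, 1.0]])


def _chain_generalized_torques(theta, dtheta, ddtheta, model: PlanarSegmentModel):
    """Torques conjugate to the absolute link angles of a hanging n-chain.

    Closed-form serial-pendulum dynamics in absolute coordinates:
    ``tau_i = J_i th''_i + sum_j P_ij [cos(th_i - th_j) th''_j
    + sin(th_i - th_j) th'_j^2] + g a_i sin th_i`` with first mass
    moments ``a_i = m_i d_i + L_i sum_{j>i} m_j``.
    """
    segs = model.segments
    n = len(segs)
    masses = np.array([s.mass for s in segs])
    lengths = np.array([s.length for s in segs])
    coms = np.array([s.com for s in segs])
    inertias = np.array([s.inertia for s in segs])
    distal_mass = np.array([masses[i + 1:].sum() for i in range(n)])
    a = masses * coms + lengths * distal_mass
    J = inertias + masses * coms ** 2 + lengths ** 2 * distal_mass

    tau = J * ddtheta + model.gravity * a * np.sin(theta)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            P = lengths[i] * a[j] if i < j else lengths[j] * a[i]
            d = theta[..., i] - theta[..., j]
            tau[..., i] += P * (np.cos(d) * ddtheta[..., j]
                                + np.sin(d) * dtheta[..., j] ** 2)
    return tau


def planar_inverse_dynamics(joint_angles, joint_velocities, joint_accelerations,
                            segment_model: PlanarSegmentModel) -> np.ndarray:
    """Net joint torques of the suspended planar three-link leg.

    Accepts ``(n, 3)`` arrays (or ``(3,)`` for a single sample) of joint
    angles, velocities and accelerations and returns torques of the same
    leading shape. With zero velocities and accelerations the result is
    the pure gravitational torque.
    """
    q = np.atleast_2d(np.asarray(joint_angles, dtype=float))
    if joint_velocities is None or joint_accelerations is None:
        raise InvalidArgumentError(
            "velocities and accelerations are required for inverse dynamics")
    qd = np.atleast_2d(np.asarray(joint_velocities, dtype=float))
    qdd = np.atleast_2d(np.asarray(joint_accelerations, dtype=float))
    if not (q.shape == qd.shape == qdd.shape) or q.shape[1] != 3:
        raise InvalidArgumentError("kinematics must share shape (n, 3)")

    theta = q @ _Q_TO_THETA.T + _THETA_OFFSET
    dtheta = qd @ _Q_TO_THETA.T
    ddtheta = qdd @ _Q_TO_THETA.T
    tau_theta = _chain_generalized_torques(theta, dtheta, ddtheta, segment_model)
    # tau_q = Jacobian^T tau_theta ; joint k collects all distal links
    tau_q = tau_theta @ _Q_TO_THETA
    out = tau_q if np.asarray(joint_angles).ndim == 2 else tau_q[0]
    return out


# ---------------------------------------------------------------------------
# Trial I/O
# ---------------------------------------------------------------------------

_META_PREFIX = "# coact-trial"


def _expected_columns(muscle_names) -> list[str]:
    cols = ["time"]
    cols += [f"q_{j}" for j in JOINTS]
    cols += [f"qd_{j}" for j in JOINTS]
    cols += [f"qdd_{j}" for j in JOINTS]
    cols += [f"T_{j}" for j in JOINTS]
    cols += [f"lm_{m}" for m in muscle_names]
    cols += [f"vm_{m}" for m in muscle_names]
    cols += [f"r_{j}_{m}" for j in JOINTS for m in muscle_names]
    return cols


def _trial_from_frame(df: pd.DataFrame, cycle_duration: float,
                      in_degrees: bool = False) -> GaitTrial:
    expected = _expected_columns(MUSCLES)
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SchemaError(f"unknown column(s): {unknown[:5]}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing[:5]}")
    time = df["time"].to_numpy(dtype=float)
    if np.any(np.diff(time) <= 0):
        raise DataError("non-monotone time column")
    ang = np.pi / 180.0 if in_degrees else 1.0

    def block(prefix, names):
        return np.column_stack([df[f"{prefix}_{x}"].to_numpy(dtype=float)
                                for x in names])

    arms = np.zeros((len(df), len(JOINTS), len(MUSCLES)))
    for k, j in enumerate(JOINTS):
        for i, m in enumerate(MUSCLES):
            arms[:, k, i] = df[f"r_{j}_{m}"].to_numpy(dtype=float)
    return GaitTrial(
        time=time,
        joint_angles=block("q", JOINTS) * ang,
        joint_velocities=block("qd", JOINTS) * ang,
        joint_accelerations=block("qdd", JOINTS) * ang,
        net_torques=block("T", JOINTS),
        muscle_lengths=block("lm", MUSCLES),
        muscle_velocities=block("vm", MUSCLES),
        moment_arms=arms,
        cycle_duration=cycle_duration,
    )


def write_trial(trial: GaitTrial, path, dialect: str = "csv",
                overwrite: bool = True) -> None:
    """Write a trial to ``path`` as CSV or OpenSim-storage-style text.

    Floats are written with 17 significant digits so the CSV dialect
    round-trips IEEE doubles bit-comparably.
    """
    if trial.n_samples == 0:
        raise InvalidArgumentError("refusing to write an empty trial")
    if os.path.exists(path) and not overwrite:
        raise InvalidArgumentError(f"{path} exists and overwrite=False")
    df = trial.to_dataframe()
    if dialect == "csv":
        buf = io.StringIO()
        buf.write(f"{_META_PREFIX} cycle_duration={trial.cycle_duration!r} "
                  "angle_unit=rad\n")
        df.to_csv(buf, index=False, float_format="%.17g")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    elif dialect == "opensim_storage":
        with open(path, "w") as fh:
            fh.write("coact_trial\nversion=1\n")
            fh.write(f"nRows={len(df)}\nnColumns={len(df.columns)}\n")
            fh.write(f"cycle_duration={trial.cycle_duration!r}\n")
            fh.write("inDegrees=no\nendheader\n")
            fh.write("\t".join(df.columns) + "\n")
            np.savetxt(fh, df.to_numpy(), fmt="%.17g", delimiter="\t")
    else:
        raise InvalidArgumentError(f"unknown dialect: {dialect!r}")


def read_trial(path, dialect: str = "csv") -> GaitTrial:
    """Read a trial written by :func:`write_trial` (or compatible files).

    The storage dialect parses header lines up to the literal line
    ``endheader``; ``nRows``/``nColumns`` are honoured and checked
    against the body. The first body column must be ``time``.
    """
    if dialect == "csv":
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith(_META_PREFIX):
                for tok in first[len(_META_PREFIX):].split():
                    k, _, v = tok.partition("=")
                    meta[k] = v
                body = fh.read()
            else:
                body = first + fh.read()
        df = pd.read_csv(io.StringIO(body), float_precision="round_trip")
        cycle = float(meta.get("cycle_duration", "nan"))
        if not np.isfinite(cycle):
            t = df["time"].to_numpy(dtype=float)
            cycle = float(t[-1] - t[0])
        in_deg = meta.get("angle_unit", "rad") == "deg"
        return _trial_from_frame(df, cycle, in_degrees=in_deg)
    if dialect == "opensim_storage":
        header: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line == "endheader":
                    break
                if "=" in line:
                    k, _, v = line.partition("=")
                    header[k.strip()] = v.strip()
            else:
                raise SchemaError("no 'endheader' line found")
            cols = fh.readline().split()
            if not cols or cols[0] != "time":
                raise SchemaError("first storage column must be 'time'")
            body = pd.read_csv(fh, sep=r"\s+", header=None, names=cols,
                               float_precision="round_trip")
        n_rows = int(header.get("nRows", len(body)))
        n_cols = int(header.get("nColumns", len(cols)))
        if len(body) != n_rows:
            raise DataError(
                f"body has {len(body)} rows but header declares nRows={n_rows}")
        if len(cols) != n_cols:
            raise DataError(
                f"body has {len(cols)} columns but header declares "
                f"nColumns={n_cols}")
        cycle = float(header.get("cycle_duration", "nan"))
        if not np.isfinite(cycle):
            t = body["time"].to_numpy(dtype=float)
            cycle = float(t.iloc[-1] - t.iloc[0]) if hasattr(t, "iloc") else float(t[-1] - t[0])
        in_deg = header.get("inDegrees", "no").lower() in ("yes", "true", "1")
        return _trial_from_frame(body, cycle, in_degrees=in_deg)
    raise InvalidArgumentError(f"unknown dialect: {dialect!r}")
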