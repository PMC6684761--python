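"""Synthetic gait generation, planar inverse dynamics and trial I/O."""

import numpy as np
import pytest

from coact.errors import DataError, InvalidArgumentError, SchemaError
from coact.gait_model import (DEFAULT_FOURIER, FourierSeries, GaitTrial,
                              MuscleGeometry, PlanarSegmentModel, Segment,
                              generate_normative_gait,
                              planar_inverse_dynamics, read_trial,
                              write_trial)
from coact.muscles import ACTIONS, JOINTS, MUSCLES


def _near_massless_distal(thigh_like=None):
    """Chain whose shank/foot are dynamically negligible: behaves as a
    single pendulum at the hip."""
    eps = Segment(mass=1e-12, length=0.4, com=0.2, inertia=1e-14)
    thigh = thigh_like or Segment(mass=8.0, length=0.42, com=0.18,
                                  inertia=0.12)
    return PlanarSegmentModel(thigh=thigh, shank=eps, foot=eps)


class TestGenerator:
    def test_invariants_and_periodicity(self, trial):
        trial.validate()
        # angles return to their start after one full cycle
        assert np.allclose(trial.joint_angles[0], trial.joint_angles[-1],
                           atol=1e-9)
        assert np.allclose(trial.joint_velocities[0],
                           trial.joint_velocities[-1], atol=1e-9)

    def test_muscle_velocity_is_length_derivative(self, trial):
        # analytic identity: vm = -sum_k r_k(q_k) qd_k
        expected = -np.einsum("skm,sk->sm", trial.moment_arms,
                              trial.joint_velocities)
        assert np.allclose(trial.muscle_velocities, expected, atol=1e-12)
        # and numerically, d(lm)/dt matches vm through central differences
        dt = trial.dt
        fd = (trial.muscle_lengths[2:] - trial.muscle_lengths[:-2]) / (2 * dt)
        scale = np.max(np.abs(trial.muscle_velocities))
        assert np.max(np.abs(fd - trial.muscle_velocities[1:-1])) < 1e-2 * scale

    def test_zero_fourier_is_static_gravity(self, segment_model, geometry):
        flat = {j: FourierSeries(a0=0.2) for j in JOINTS}
        trial = generate_normative_gait(segment_model, geometry,
                                        n_samples=33, cycle_duration=1.0,
                                        fourier=flat)
        assert np.allclose(trial.joint_velocities, 0.0)
        assert np.allclose(trial.joint_accelerations, 0.0)
        static = planar_inverse_dynamics(trial.joint_angles,
                                         np.zeros_like(trial.joint_angles),
                                         np.zeros_like(trial.joint_angles),
                                         segment_model)
        assert np.allclose(trial.net_torques, static)
        assert np.ptp(trial.net_torques, axis=0).max() < 1e-12

    def test_constant_moment_arm_length_change(self, geometry, segment_model):
        # monoarticular hip muscle with constant arm r: dl = -r * dq_hip
        trial = generate_normative_gait(segment_model, geometry,
                                        n_samples=51, cycle_duration=1.0)
        i = MUSCLES.index("gluteus_maximus_1")
        r = float(geometry.moment_arm_coeffs["gluteus_maximus_1"]["hip"][0])
        dq = trial.joint_angles[:, 0] - trial.joint_angles[0, 0]
        dl = trial.muscle_lengths[:, i] - trial.muscle_lengths[0, i]
        assert np.allclose(dl, -r * dq, atol=1e-12)

    def test_default_knee_excursion(self, trial):
        # peak-to-peak of the documented default knee series, evaluated
        # independently on a dense grid
        s = DEFAULT_FOURIER["knee"]
        tt = np.linspace(0.0, 1.2, 20001)
        w = 2 * np.pi / 1.2
        q = np.full_like(tt, s.a0)
        for h in range(1, 3):
            a = s.cos[h - 1] if h <= len(s.cos) else 0.0
            b = s.sin[h - 1] if h <= len(s.sin) else 0.0
            q += a * np.cos(h * w * tt) + b * np.sin(h * w * tt)
        expected = q.max() - q.min()
        got = np.ptp(trial.joint_angles[:, 1])
        assert got == pytest.approx(expected, rel=1e-3)

    def test_identical_seed_identical_trial(self, segment_model, geometry):
        t1 = generate_normative_gait(segment_model, geometry, seed=7,
                                     variability=0.02)
        t2 = generate_normative_gait(segment_model, geometry, seed=7,
                                     variability=0.02)
        t3 = generate_normative_gait(segment_model, geometry, seed=8,
                                     variability=0.02)
        assert np.array_equal(t1.joint_angles, t2.joint_angles)
        assert not np.array_equal(t1.joint_angles, t3.joint_angles)

    @pytest.mark.parametrize("kw", [{"n_samples": 8}, {"cycle_duration": 0.0},
                                    {"cycle_duration": -1.0}])
    def test_invalid_arguments(self, segment_model, geometry, kw):
        with pytest.raises(InvalidArgumentError):
            generate_normative_gait(segment_model, geometry, **kw)


class TestInverseDynamics:
    def test_single_link_hanging_is_torque_free(self):
        model = _near_massless_distal()
        q = np.zeros((1, 3))
        tau = planar_inverse_dynamics(q, np.zeros_like(q), np.zeros_like(q),
                                      model)
        assert abs(tau[0, 0]) < 1e-9

    def test_single_link_horizontal_gravity_moment(self):
        model = _near_massless_distal()
        q = np.array([[np.pi / 2, 0.0, 0.0]])
        tau = planar_inverse_dynamics(q, np.zeros_like(q), np.zeros_like(q),
                                      model)
        expected = model.thigh.mass * model.gravity * model.thigh.com
        assert tau[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_matches_symbolic_lagrangian_oracle(self, segment_model):
        """Random sinusoidal 3-link motion against an independently derived
        Euler-Lagrange oracle (symbolic differentiation of the chain's
        kinetic and potential energy)."""
        sp = pytest.importorskip("sympy")
        q_s = sp.symbols("q0:3")
        qd_s = sp.symbols("qd0:3")
        qdd_s = sp.symbols("qdd0:3")
        theta = [q_s[0], q_s[0] - q_s[1], q_s[0] - q_s[1] + q_s[2] + sp.pi / 2]
        segs = segment_model.segments
        g = segment_model.gravity
        # chain positions built from scratch (independent of the package)
        px, py = sp.Integer(0), sp.Integer(0)
        L = sp.Integer(0)
        for k, seg in enumerate(segs):
            cx = px + seg.com * sp.sin(theta[k])
            cy = py - seg.com * sp.cos(theta[k])
            vx = sum(sp.diff(cx, q_s[j]) * qd_s[j] for j in range(3))
            vy = sum(sp.diff(cy, q_s[j]) * qd_s[j] for j in range(3))
            om = sum(sp.diff(theta[k], q_s[j]) * qd_s[j] for j in range(3))
            L += (sp.Rational(1, 2) * seg.mass * (vx ** 2 + vy ** 2)
                  + sp.Rational(1, 2) * seg.inertia * om ** 2
                  - seg.mass * g * cy)
            px = px + seg.length * sp.sin(theta[k])
            py = py - seg.length * sp.cos(theta[k])
        taus = []
        for i in range(3):
            dLdqd = sp.diff(L, qd_s[i])
            ddt = (sum(sp.diff(dLdqd, q_s[j]) * qd_s[j] for j in range(3))
                   + sum(sp.diff(dLdqd, qd_s[j]) * qdd_s[j] for j in range(3)))
            taus.append(sp.simplify(ddt - sp.diff(L, q_s[i])))
        oracle = sp.lambdify(q_s + qd_s + qdd_s, taus, "numpy")

        rng = np.random.default_rng(0)
        t = np.linspace(0.0, 1.0, 11)
        amp = rng.uniform(0.2, 0.6, 3)
        pha = rng.uniform(0, 2 * np.pi, 3)
        w = rng.uniform(3.0, 8.0, 3)
        q = amp * np.sin(w * t[:, None] + pha)
        qd = amp * w * np.cos(w * t[:, None] + pha)
        qdd = -amp * w ** 2 * np.sin(w * t[:, None] + pha)
        got = planar_inverse_dynamics(q, qd, qdd, segment_model)
        want = np.stack(oracle(*q.T, *qd.T, *qdd.T), axis=-1)
        scale = np.max(np.abs(want))
        assert np.max(np.abs(got - want)) < 1e-6 * scale

    def test_missing_accelerations_rejected(self, segment_model):
        q = np.zeros((4, 3))
        with pytest.raises(InvalidArgumentError):
            planar_inverse_dynamics(q, q, None, segment_model)


class TestTrialIO:
    @pytest.mark.parametrize("dialect", ["csv", "opensim_storage"])
    def test_roundtrip(self, trial, tmp_path, dialect):
        path = tmp_path / f"trial.{dialect}"
        write_trial(trial, path, dialect=dialect)
        back = read_trial(path, dialect=dialect)
        for f in ("time", "joint_angles", "joint_velocities",
                  "joint_accelerations", "net_torques", "muscle_lengths",
                  "muscle_velocities", "moment_arms"):
            assert np.array_equal(getattr(trial, f), getattr(back, f)), f
        assert back.cycle_duration == trial.cycle_duration

    def test_storage_row_count_mismatch(self, trial, tmp_path):
        path = tmp_path / "trial.sto"
        write_trial(trial, path, dialect="opensim_storage")
        lines = path.read_text().splitlines()
        del lines[-1]  # drop a body row: declared nRows no longer honored
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DataError, match="nRows"):
            read_trial(path, dialect="opensim_storage")

    def test_unknown_muscle_column_named_in_error(self, trial, tmp_path):
        path = tmp_path / "trial.csv"
        write_trial(trial, path, dialect="csv")
        text = path.read_text().replace("lm_rectus_femoris",
                                        "lm_mystery_muscle")
        path.write_text(text)
        with pytest.raises(SchemaError, match="mystery_muscle"):
            read_trial(path, dialect="csv")

    def test_non_monotone_time_rejected(self, trial, tmp_path):
        import pandas as pd
        path = tmp_path / "trial.csv"
        write_trial(trial, path, dialect="csv")
        bad = trial.to_dataframe()
        bad.loc[5, "time"] = bad.loc[2, "time"]
        with open(path, "w") as fh:
            fh.write("# coact-trial cycle_duration=1.2 angle_unit=rad\n")
            bad.to_csv(fh, index=False)
        with pytest.raises(DataError, match="time"):
            read_trial(path, dialect="csv")

    def test_overwrite_flag_and_empty_trial(self, trial, tmp_path):
        path = tmp_path / "trial.csv"
        write_trial(trial, path, dialect="csv")
        with pytest.raises(InvalidArgumentError):
            write_trial(trial, path, dialect="csv", overwrite=False)
        import dataclasses
        empty = dataclasses.replace(
            trial, time=np.empty(0), joint_angles=np.empty((0, 3)))
        with pytest.raises(InvalidArgumentError):
            write_trial(empty, tmp_path / "empty.csv")
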