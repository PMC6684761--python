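"""Hammerstein FES model: static blocks, calibration, inversion chain."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from coact.errors import (CalibrationError, ConfigurationError,
                          InvalidArgumentError)
from coact.fes_synthesis import (FrequencyParams, LinearBlockParams,
                                 RecruitmentParams, amplitude_profile,
                                 calibrate_frequency_params,
                                 forward_hammerstein, frequency_profile,
                                 frequency_scale, invert_activation_block,
                                 recruitment_scale, synthesize_fes)

RP = RecruitmentParams(u_tr=20.0, u_sat=40.0)
FP = calibrate_frequency_params(1.2, 30.0, 15.0)
LBP = LinearBlockParams(T_e=0.01, T_rise=0.022, T_fall=0.2)


class TestRecruitment:
    @pytest.mark.parametrize("U,expected", [(10.0, 0.0), (20.0, 0.0),
                                            (30.0, 0.5), (40.0, 1.0),
                                            (45.0, 1.0)])
    def test_three_regions(self, U, expected):
        assert recruitment_scale(U, RP) == pytest.approx(expected)

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    def test_monotone_nondecreasing(self, u1, u2):
        lo, hi = sorted((u1, u2))
        assert recruitment_scale(lo, RP) <= recruitment_scale(hi, RP) + 1e-15

    def test_negative_intensity_rejected(self):
        with pytest.raises(InvalidArgumentError):
            recruitment_scale(-1.0, RP)

    def test_atypical_amplitude_warns(self):
        with pytest.warns(UserWarning):
            RecruitmentParams(u_tr=5.0, u_sat=60.0)


class TestFrequencySigmoid:
    def test_calibration_closed_form_values(self):
        # k2 = 1.2, f_CF = 30 Hz, R = 15 Hz
        assert FP.f0 == pytest.approx(
            15.0 * np.log(0.2 * np.exp(2.0) - 1.2), rel=1e-12)
        assert FP.f0 == pytest.approx(-19.213, abs=1e-3)
        assert FP.k1 == pytest.approx(-1.2 * np.exp(-FP.f0 / 15.0), rel=1e-12)
        assert FP.k1 == pytest.approx(-4.3196, abs=1e-3)

    def test_boundary_conditions(self):
        assert frequency_scale(0.0, FP) == pytest.approx(0.0, abs=1e-12)
        assert frequency_scale(FP.f_cf, FP) == pytest.approx(1.0, abs=1e-12)

    def test_supremum_is_k2_ratio(self):
        assert frequency_scale(1e6, FP) == pytest.approx(FP.k2_ratio)

    @given(st.floats(1.05, 3.0), st.floats(20.0, 60.0), st.floats(5.0, 30.0))
    def test_boundary_conditions_randomized(self, k2, f_cf, R):
        assume((k2 - 1.0) * np.exp(f_cf / R) - k2 > 1e-9)
        fp = calibrate_frequency_params(k2, f_cf, R)
        assert abs(frequency_scale(0.0, fp)) < 1e-12
        assert abs(frequency_scale(f_cf, fp) - 1.0) < 1e-12

    def test_monotone_increasing(self):
        f = np.linspace(0.0, 100.0, 400)
        s = frequency_scale(f, FP)
        assert np.all(np.diff(s) > 0)

    def test_violated_inequality_named(self):
        with pytest.raises(CalibrationError, match="f_CF"):
            calibrate_frequency_params(1.2, 1.0, 15.0)
        with pytest.raises(CalibrationError):
            calibrate_frequency_params(0.9, 30.0, 15.0)


class TestInvertActivationBlock:
    def test_constant_activation_is_steady_state(self):
        e = invert_activation_block(np.full(40, 0.6), LBP, dt=0.01)
        assert np.allclose(e, 0.6, atol=1e-12)

    def test_zero_activation_zero_excitation(self):
        e = invert_activation_block(np.zeros(40), LBP, dt=0.01)
        assert np.allclose(e, 0.0, atol=1e-12)

    def test_sine_matches_analytic_derivatives(self):
        # equal rise/fall constants make the phase rule immaterial
        lbp = LinearBlockParams(T_e=0.01, T_rise=0.05, T_fall=0.05)
        c1, c2 = lbp.coeffs(rising=True)
        T, n = 1.0, 501
        t = np.linspace(0.0, T, n)
        dt = t[1] - t[0]
        A, w = 0.3, 2 * np.pi / T
        a = 0.5 + A * np.sin(w * t)
        e = invert_activation_block(a, lbp, dt)
        analytic = (c1 * (-A * w ** 2 * np.sin(w * t))
                    + c2 * (A * w * np.cos(w * t)) + a)
        # backward differences carry an O(dt) bias
        interior = slice(5, None)
        assert np.max(np.abs(e[interior] - analytic[interior])) < 10 * dt

    def test_short_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            invert_activation_block(np.array([0.1, 0.2, 0.3]), LBP, dt=0.01)


class TestProfiles:
    def test_amplitude_zero_excitation_is_off(self):
        prof = amplitude_profile(np.zeros(10), 30.0, RP, FP)
        assert np.allclose(prof.command, 0.0)
        assert not prof.mask.any()

    def test_amplitude_saturation_maps_to_u_sat(self):
        s_f = float(frequency_scale(30.0, FP))
        prof = amplitude_profile(np.full(5, s_f), 30.0, RP, FP)
        assert np.allclose(prof.command, RP.u_sat)
        assert not prof.mask.any()

    def test_amplitude_linear_branch_midpoint(self):
        s_f = float(frequency_scale(30.0, FP))
        prof = amplitude_profile(np.full(5, 0.5 * s_f), 30.0, RP, FP)
        assert np.allclose(prof.command, 30.0)

    def test_amplitude_mask_iff_out_of_range(self):
        s_f = float(frequency_scale(30.0, FP))
        e = np.array([-0.1, 0.0, 0.5 * s_f, s_f, 1.5 * s_f])
        prof = amplitude_profile(e, 30.0, RP, FP)
        assert prof.mask.tolist() == [True, False, False, False, True]

    def test_amplitude_low_fixed_frequency_rejected(self):
        # S_f <= 0 only at f = 0, which the precondition excludes
        with pytest.raises(InvalidArgumentError):
            amplitude_profile(np.zeros(4), 0.0, RP, FP)

    def test_frequency_at_unit_scaling_is_f_cf(self):
        s_u = float(recruitment_scale(30.0, RP))
        prof = frequency_profile(np.full(5, s_u), 30.0, RP, FP)
        assert np.allclose(prof.command, FP.f_cf)
        assert not prof.mask.any()

    def test_frequency_small_excitation_maps_to_low_frequency(self):
        s_u = float(recruitment_scale(30.0, RP))
        prof = frequency_profile(np.full(5, 1e-9 * s_u), 30.0, RP, FP)
        assert np.all(prof.command < 0.1)

    def test_frequency_subthreshold_amplitude_rejected(self):
        with pytest.raises(InvalidArgumentError):
            frequency_profile(np.full(5, 0.5), 15.0, RP, FP)

    @given(st.lists(st.floats(0.01, 0.55), min_size=4, max_size=30))
    def test_frequency_round_trip_identity(self, e_list):
        # S_f(f(e)) * S_u reproduces e on unmasked samples
        e = np.array(e_list)
        s_u = float(recruitment_scale(30.0, RP))
        prof = frequency_profile(e, 30.0, RP, FP)
        assume(not prof.mask.any())
        back = frequency_scale(prof.command, FP) * s_u
        assert np.max(np.abs(back - e)) < 1e-9

    def test_frequency_mask_iff_clamped(self):
        s_u = float(recruitment_scale(30.0, RP))
        e = np.array([-0.01, 0.0, 0.3, s_u * FP.k2_ratio * 1.01])
        prof = frequency_profile(e, 30.0, RP, FP)
        assert prof.mask.tolist() == [True, False, False, True]


class TestForwardHammerstein:
    def test_zero_profile_stays_at_rest(self):
        prof = amplitude_profile(np.zeros(30), 30.0, RP, FP)
        a = forward_hammerstein(prof, RP, FP, LBP, dt=0.01)
        assert np.allclose(a, 0.0, atol=1e-12)

    def test_saturating_profile_approaches_unity(self):
        # constant saturation at the critical fusion frequency: e = 1
        prof = amplitude_profile(np.full(400, 1.0), FP.f_cf, RP, FP)
        a = forward_hammerstein(prof, RP, FP, LBP, dt=0.01)
        assert a[-1] == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("mode,fixed", [("amplitude_modulated", 30.0),
                                            ("frequency_modulated", 35.0)])
    def test_round_trip_inversion(self, mode, fixed):
        T, n = 1.2, 121
        t = np.linspace(0.0, T, n)
        dt = t[1] - t[0]
        a = 0.45 + 0.2 * np.sin(2 * np.pi * t / T)
        prof = synthesize_fes(a, LBP, RP, FP, dt, mode, fixed)
        assert not prof.mask.any()
        a_rec = forward_hammerstein(prof, RP, FP, LBP, dt, a0=a[0],
                                    adot0=(a[1] - a[0]) / dt)
        rms = np.sqrt(np.mean((a_rec - a) ** 2))
        assert rms <= 1e-2
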