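"""Stimulation-profile synthesis: inverting the FES activation model.

An electrically stimulated muscle is modelled as a two-block Hammerstein
structure: a static nonlinearity mapping the stimulus intensity and
frequency to an excitation level,

    e(t) = S_u(U_stim) * S_f(f_stim),

followed by linear second-order activation dynamics

    c1 * a'' + c2 * a' + a = e,        c1 = T_e * T_rise/fall,
                                       c2 = T_rise/fall + T_e.

``S_u`` is the piecewise-linear isometric recruitment curve between a
threshold ``U_tr`` and a saturation level ``U_sat``; ``S_f`` is a
sigmoid in the stimulation frequency calibrated so that S_f(0) = 0 and
S_f(f_CF) = 1 at the critical fusion frequency. Above f_CF the sigmoid
saturates at ``k2 = F_max / F_CF > 1``, so excitations up to k2 are
representable.

Given an activation trajectory from the load-sharing step, the chain is
inverted: the linear block by backward differences (spline-filling the
first samples that lack backward history), then the static block either
for the intensity at a fixed frequency (amplitude-modulated profile) or
for the frequency at a fixed intensity (frequency-modulated profile).
Out-of-range samples are clamped and flagged in a mask. The forward
model is provided for round-trip validation.

Naming note: the sigmoid constants (k1, k2) and the linear-block
constants are distinct quantities that share symbols in the source
literature; the linear-block pair is named (c1, c2) here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline

from .errors import (CalibrationError, ConfigurationError,
                     InvalidArgumentError)
from .muscle_model import MuscleParams


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecruitmentParams:
    """Isometric recruitment curve: threshold and saturation intensity.

    ``mode`` tags the unit of the intensity axis (stimulation amplitude
    in mA or pulse width in microseconds); it must be consistent within
    a run. Typical amplitudes lie in 10-50 mA; values outside trigger a
    validation warning, not an error.
    """

    u_tr: float
    u_sat: float
    mode: str = "amplitude_mA"

    def __post_init__(self):
        if not 0 < self.u_tr < self.u_sat:
            raise InvalidArgumentError("need 0 < u_tr < u_sat")
        if self.mode not in ("amplitude_mA", "pulse_width_us"):
            raise InvalidArgumentError(f"unknown mode: {self.mode!r}")
        if self.mode == "amplitude_mA" and not (10.0 <= self.u_tr and
                                                self.u_sat <= 50.0):
            warnings.warn(
                "stimulation amplitudes outside the typical 10-50 mA range",
                stacklevel=3)


@dataclass(frozen=True)
class FrequencyParams:
    """Calibrated frequency-force sigmoid S_f.

    Construct through :func:`calibrate_frequency_params`, which derives
    ``k1`` and ``f0`` from the boundary conditions S_f(0) = 0 and
    S_f(f_CF) = 1.
    """

    k2_ratio: float        # F_max / F_CF, > 1
    f_cf: float            # Hz, critical fusion frequency
    R: float               # Hz, sigmoid shape constant
    k1: float              # derived
    f0: float              # Hz, derived


def calibrate_frequency_params(k2_ratio: float, f_cf: float,
                               R: float = 15.0) -> FrequencyParams:
    """Derive the sigmoid constants from its two boundary conditions.

    ``f0 = R ln[(k2 - 1) e^{f_CF/R} - k2]`` and ``k1 = -k2 e^{-f0/R}``;
    the logarithm argument must be positive, which bounds the admissible
    (k2_ratio, f_CF, R) combinations.
    """
    if k2_ratio <= 1.0:
        raise CalibrationError("k2_ratio must exceed 1 (F_max > F_CF)")
    if f_cf <= 0 or R <= 0:
        raise CalibrationError("f_cf and R must be positive")
    arg = (k2_ratio - 1.0) * np.exp(f_cf / R) - k2_ratio
    if arg <= 0:
        raise CalibrationError(
            "calibration requires (k2-1) e^{f_CF/R} - k2 > 0; got "
            f"{arg:.4g} for k2={k2_ratio}, f_CF={f_cf}, R={R}")
    f0 = R * np.log(arg)
    k1 = -k2_ratio * np.exp(-f0 / R)
    return FrequencyParams(k2_ratio=k2_ratio, f_cf=f_cf, R=R,
                           k1=float(k1), f0=float(f0))


@dataclass(frozen=True)
class LinearBlockParams:
    """Second-order activation block constants.

    ``c1 = T_e * T_rise/fall`` and ``c2 = T_rise/fall + T_e``; which of
    T_rise / T_fall applies is chosen per sample by ``phase_rule``:
    "auto" uses T_rise while the excitation drives activation up
    (e >= a) and T_fall otherwise; "rise" / "fall" pin one constant.
    """

    T_e: float
    T_rise: float
    T_fall: float
    phase_rule: str = "auto"

    def __post_init__(self):
        if min(self.T_e, self.T_rise, self.T_fall) <= 0:
            raise InvalidArgumentError("time constants must be > 0")
        if self.phase_rule not in ("auto", "rise", "fall"):
            raise InvalidArgumentError(f"unknown phase_rule: {self.phase_rule!r}")

    @classmethod
    def from_muscle(cls, p: MuscleParams,
                    phase_rule: str = "auto") -> "LinearBlockParams":
        return cls(T_e=p.T_e, T_rise=p.T_rise, T_fall=p.T_fall,
                   phase_rule=phase_rule)

    def coeffs(self, rising: bool) -> tuple[float, float]:
        T = self.T_rise if rising else self.T_fall
        return self.T_e * T, T + self.T_e


@dataclass
class FESProfile:
    """Stimulation command trajectory for one muscle.

    ``mode`` is "amplitude_modulated" (command = intensity, frequency
    fixed) or "frequency_modulated" (command = frequency in Hz,
    intensity fixed). ``mask`` is True wherever the pre-clamp command
    left the admissible interval.
    """

    mode: str
    fixed_value: float
    command: np.ndarray
    mask: np.ndarray
    time: np.ndarray | None = None
    muscle: str | None = None


# ---------------------------------------------------------------------------
# Static blocks
# ---------------------------------------------------------------------------

def recruitment_scale(U, p: RecruitmentParams):
    """Fraction of fibers recruited at stimulus intensity ``U``.

    Zero below the threshold, linear in between, one above saturation;
    continuous and monotone nondecreasing.
    """
    U = np.asarray(U, dtype=float)
    if np.any(U < 0):
        raise InvalidArgumentError("stimulus intensity must be >= 0")
    return np.clip((U - p.u_tr) / (p.u_sat - p.u_tr), 0.0, 1.0)


def frequency_scale(f, p: FrequencyParams):
    """Frequency scaling factor S_f(f) of the calibrated sigmoid."""
    f = np.asarray(f, dtype=float)
    z = np.minimum((f - p.f0) / p.R, 700.0)  # avoid spurious overflow
    return (p.k1 - p.k2_ratio) / (1.0 + np.exp(z)) + p.k2_ratio


def invert_frequency_scale(S_f, p: FrequencyParams):
    """Frequency at which the sigmoid attains ``S_f`` (its interior range).

    Valid for S_f in (k1, k2); S_f in (0, k2) maps to nonnegative
    frequencies. Returns NaN outside the invertible range.
    """
    S_f = np.asarray(S_f, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = (p.k1 - p.k2_ratio) / (S_f - p.k2_ratio) - 1.0
        f = p.f0 + p.R * np.log(arg)
    return np.where((S_f > p.k1) & (S_f < p.k2_ratio), f, np.nan)


# ---------------------------------------------------------------------------
# Linear block inversion
# ---------------------------------------------------------------------------

def invert_activation_block(a, p: LinearBlockParams, dt: float,
                            smooth: bool = False) -> np.ndarray:
    """Excitation series reproducing an activation trajectory.

    Computes ``e = c1 a'' + c2 a' + a`` with first and second backward
    differences. The first two samples, which lack backward history, are
    filled by extrapolating an order-3 spline fitted to the first four
    interior values. ``smooth`` optionally applies a zero-phase 3-point
    binomial filter to ``a`` first (off by default).

    The result is the mathematically required excitation; it may exceed
    the representable range of the static blocks (that is handled, with
    masks, by the profile builders).
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 1 or a.shape[0] < 4:
        raise InvalidArgumentError("activation series must have length >= 4")
    if dt <= 0:
        raise InvalidArgumentError("dt must be > 0")
    if smooth:
        pad = np.concatenate([a[:1], a, a[-1:]])
        a = 0.25 * pad[:-2] + 0.5 * pad[1:-1] + 0.25 * pad[2:]

    adot = np.empty_like(a)
    addot = np.empty_like(a)
    adot[1:] = (a[1:] - a[:-1]) / dt
    addot[2:] = (a[2:] - 2.0 * a[1:-1] + a[:-2]) / dt ** 2
    adot[0] = addot[0] = addot[1] = 0.0  # placeholders, overwritten below

    c1r, c2r = p.coeffs(rising=True)
    c1f, c2f = p.coeffs(rising=False)
    if p.phase_rule == "rise":
        e = c1r * addot + c2r * adot + a
    elif p.phase_rule == "fall":
        e = c1f * addot + c2f * adot + a
    else:
        e_r = c1r * addot + c2r * adot + a
        e_f = c1f * addot + c2f * adot + a
        # self-consistent choice: rise constants iff they predict e >= a;
        # fall back on the slope sign when both or neither agree
        e = np.where(e_r >= a, e_r, np.where(e_f < a, e_f,
                     np.where(adot >= 0.0, e_r, e_f)))

    k = np.arange(2, 6, dtype=float)
    spl = InterpolatedUnivariateSpline(k, e[2:6], k=3, ext=0)
    e[:2] = spl(np.array([0.0, 1.0]))
    return e


# ---------------------------------------------------------------------------
# Profile builders (static-block inversion)
# ---------------------------------------------------------------------------

def amplitude_profile(e, f_fixed: float, rp: RecruitmentParams,
                      fp: FrequencyParams, time=None, muscle=None,
                      report_subthreshold: bool = False) -> FESProfile:
    """Amplitude-modulated profile at a fixed stimulation frequency.

    With ``S_f(f_fixed)`` known, the required recruitment is
    ``S_u = e / S_f`` (clipped to [0, 1] with mask) and the intensity
    follows from the linear branch of the recruitment curve. Where the
    muscle is off (S_u = 0) the commanded intensity is reported as 0
    rather than the mathematical inverse ``u_tr``, so no sub-threshold
    current is commanded; set ``report_subthreshold`` to recover u_tr.
    """
    if f_fixed <= 0:
        raise InvalidArgumentError("f_fixed must be > 0")
    e = np.asarray(e, dtype=float)
    s_f = float(frequency_scale(f_fixed, fp))
    if s_f <= 0:
        raise ConfigurationError(
            f"S_f(f_fixed={f_fixed}) = {s_f:.4g} <= 0; pick a higher "
            "fixed frequency")
    s_u_raw = e / s_f
    s_u = np.clip(s_u_raw, 0.0, 1.0)
    mask = (s_u_raw < 0.0) | (s_u_raw > 1.0)
    U = rp.u_tr + s_u * (rp.u_sat - rp.u_tr)
    if not report_subthreshold:
        U = np.where(s_u <= 0.0, 0.0, U)
    return FESProfile(mode="amplitude_modulated", fixed_value=float(f_fixed),
                      command=U, mask=mask, time=time, muscle=muscle)


def frequency_profile(e, U_fixed: float, rp: RecruitmentParams,
                      fp: FrequencyParams, time=None, muscle=None,
                      f_ceiling: float = 50.0) -> FESProfile:
    """Frequency-modulated profile at a fixed stimulation intensity.

    With ``S_u(U_fixed)`` known, the required frequency scaling is
    ``S_f = e / S_u``, inverted through the sigmoid wherever it lies in
    the invertible range (0, k2); outside, the command is clamped to
    [0, f_ceiling] and masked.
    """
    s_u = float(recruitment_scale(U_fixed, rp))
    if s_u <= 0.0:
        raise InvalidArgumentError(
            "U_fixed must exceed the recruitment threshold u_tr")
    e = np.asarray(e, dtype=float)
    s_f = e / s_u
    f = np.zeros_like(e)
    mask = np.zeros(e.shape, dtype=bool)

    inner = (s_f > 0.0) & (s_f < fp.k2_ratio)
    f[inner] = invert_frequency_scale(s_f[inner], fp)
    mask |= s_f < 0.0           # negative excitation: not representable
    mask |= s_f >= fp.k2_ratio  # beyond the sigmoid supremum
    f[s_f >= fp.k2_ratio] = f_ceiling
    over = f > f_ceiling
    mask |= over
    f = np.clip(f, 0.0, f_ceiling)
    return FESProfile(mode="frequency_modulated", fixed_value=float(U_fixed),
                      command=f, mask=mask, time=time, muscle=muscle)


def synthesize_fes(a, lbp: LinearBlockParams, rp: RecruitmentParams,
                   fp: FrequencyParams, dt: float, mode: str,
                   fixed_value: float, time=None, muscle=None) -> FESProfile:
    """Full inversion chain: activation -> excitation -> stimulation."""
    e = invert_activation_block(a, lbp, dt)
    if mode == "amplitude_modulated":
        return amplitude_profile(e, fixed_value, rp, fp, time=time,
                                 muscle=muscle)
    if mode == "frequency_modulated":
        return frequency_profile(e, fixed_value, rp, fp, time=time,
                                 muscle=muscle)
    raise InvalidArgumentError(f"unknown FES mode: {mode!r}")


# ---------------------------------------------------------------------------
# Forward model (validation oracle for the inversion chain)
# ---------------------------------------------------------------------------

def excitation_from_profile(profile: FESProfile, rp: RecruitmentParams,
                            fp: FrequencyParams) -> np.ndarray:
    """Static-block output e = S_u * S_f for a stimulation profile."""
    if profile.mode == "amplitude_modulated":
        s_f = float(frequency_scale(profile.fixed_value, fp))
        return recruitment_scale(profile.command, rp) * s_f
    if profile.mode == "frequency_modulated":
        s_u = float(recruitment_scale(profile.fixed_value, rp))
        return s_u * frequency_scale(profile.command, fp)
    raise InvalidArgumentError(f"unknown FES mode: {profile.mode!r}")


def forward_hammerstein(profile: FESProfile, rp: RecruitmentParams,
                        fp: FrequencyParams, p: LinearBlockParams,
                        dt: float, a0: float = 0.0, adot0: float = 0.0,
                        substep: float = 1e-3) -> np.ndarray:
    """Simulate the activation produced by a stimulation profile.

    Evaluates the static blocks, then integrates the second-order linear
    block with classical RK4 at an internal substep (excitation linearly
    interpolated between samples), starting from (a0, adot0) — rest by
    default. Serves as the independent forward oracle when validating
    the inversion chain.
    """
    e = excitation_from_profile(profile, rp, fp)
    n = len(e)
    n_sub = max(1, int(np.ceil(dt / substep)))
    h = dt / n_sub
    c1r, c2r = p.coeffs(rising=True)
    c1f, c2f = p.coeffs(rising=False)

    def deriv(state, e_t):
        a, v = state
        if p.phase_rule == "rise":
            c1, c2 = c1r, c2r
        elif p.phase_rule == "fall":
            c1, c2 = c1f, c2f
        else:
            c1, c2 = (c1r, c2r) if e_t >= a else (c1f, c2f)
        return np.array([v, (e_t - a - c2 * v) / c1])

    out = np.empty(n)
    state = np.array([a0, adot0], dtype=float)
    out[0] = a0
    for i in range(n - 1):
        for s in range(n_sub):
            frac0 = s / n_sub
            e0 = e[i] + (e[i + 1] - e[i]) * frac0
            e_half = e[i] + (e[i + 1] - e[i]) * (frac0 + 0.5 / n_sub)
            e1 = e[i] + (e[i + 1] - e[i]) * (frac0 + 1.0 / n_sub)
            k1 = deriv(state, e0)
            k2 = deriv(state + 0.5 * h * k1, e_half)
            k3 = deriv(state + 0.5 * h * k2, e_half)
            k4 = deriv(state + h * k3, e1)
            state = state + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i + 1] = state[0]
    return out
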