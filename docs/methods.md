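# Methods

`coact` designs the cooperative actuation of a hybrid hip–knee–ankle–foot
orthosis: for each degree of freedom, an electromechanical motor and a set
of electrically stimulated muscles must together produce the net joint
torque of a desired (normative) gait, while each stimulation profile
remains physiologically meaningful for the wearer. This note describes the
models, the assumptions behind them, the defaults, and the limits of what
the synthetic validation shows.

## Pipeline overview

1. **Gait input** — joint kinematics, net joint torques, muscle-tendon
   lengths/velocities and moment arms over one cycle (read from file, or
   synthesized; see below).
2. **Maximum achievable forces** — the rigid-tendon Hill model evaluated at
   full activation along the trial gives each muscle's force envelope
   f\*(t) and its cycle maximum f_max (step 1 of the physiological static
   optimization).
3. **Load sharing** — at every sample, activations a ∈ [0,1]^15 and motor
   torques T_o within actuator bounds are chosen so that
   R·[a⊙F\*, T_o] = T, minimizing one of four cost functions (step 2).
4. **FES synthesis** — the activation trajectories are pushed backwards
   through the two-block Hammerstein model of artificially activated
   muscle to obtain stimulation commands (amplitude- or
   frequency-modulated).
5. **Fatigue compensation** — the cycle is repeated over a horizon while a
   capacity factor ψ erodes muscle force; the load sharing is re-solved
   with ψ-weighted costs and ψ-scaled capacity, and the FES profiles are
   re-inverted. Total joint torque is preserved; the motors absorb the
   shortfall.

## Synthetic gait generator

Real normative recordings require a motion-capture pipeline, so the
package ships a generator that produces a *dynamically and geometrically
consistent* single-leg trial:

* Joint angles are truncated Fourier series in cycle phase. The defaults
  (radians; hip `0.15 + 0.32cos + 0.10sin`, knee
  `0.50 − 0.25cos − 0.15cos2 + 0.05sin + 0.08sin2`, ankle
  `−0.10cos + 0.12sin`) approximate adult sagittal gait: hip flexion
  −11°…28°, a double-bump knee flexion pattern peaking near 49°, ankle
  ±9°. Velocities and accelerations are exact analytic derivatives, so the
  cycle is exactly periodic. An optional seeded amplitude jitter
  (`variability`, default 0) produces trial-to-trial variation.
* Net torques come from a suspended planar three-link chain
  (thigh/shank/foot; closed-form serial-pendulum dynamics in absolute
  angles) with segment parameters from standard adult anthropometric
  regressions scaled to subject mass (default 72.6 kg) and height
  (1.70 m). Ground contact is deliberately not modelled: the downstream
  method only needs a consistent torque demand T(t), and the suspended
  (swing-style) chain supplies one with realistic magnitudes
  (hip ≈ ±20 N·m). Consequences: stance-phase torque peaks of real
  walking (ankle push-off ≈ 1.5 N·m/kg) are absent, so absolute torque
  levels are smaller and smoother than in recorded gait.
* Muscle geometry: moment arms are low-order polynomials in joint angle
  (defaults: signed constants at anatomical magnitudes, 1.5–6 cm), and
  fiber length is the reference length (default: optimal fiber length)
  minus the angle-integral of the moment arm over each spanned joint, so
  lengths, velocities and moment arms are mutually consistent by
  construction. The muscle set is the classic 15-muscle sagittal leg;
  the short head of biceps femoris is carried in the hamstring group as a
  hip extensor + knee flexor. Anatomically it crosses only the knee; the
  effect of the extra ~2 cm hip moment arm on the hip torque budget is
  negligible next to gluteals and the long hamstrings.

Passing tests on this generator therefore demonstrate the *method* —
consistency, optimality, invertibility, fatigue compensation — not
fidelity to any particular recorded subject.

Sign conventions: hip flexion, knee flexion, ankle dorsiflexion positive;
a muscle's moment arm is signed so that moment arm × force produces torque
of its anatomical action. Units are SI throughout; degrees appear only at
the file boundary under an explicit header flag. Sampling default is 101
samples/cycle (percent-of-cycle convention), cycle duration 1.2 s.

Only one leg is modelled. The three joints of the leg are solved
*simultaneously* because seven of the fifteen muscles are biarticular;
the two legs share no muscle, so a bilateral trial is simply two
phase-shifted single-leg solves.

## Muscle model

Rigid tendon: fiber kinematics equal musculotendon kinematics, so the
contraction dynamics reduce to an algebraic Hill relation,
`f = f0 (a·fl(l̃)·fv(ṽ) + fp(l̃))`, evaluated sample-wise. Curves: Gaussian
active force–length (width 0.45), Hill hyperbola force–velocity with a
C¹-smooth saturating eccentric branch (plateau 1.4·f0, curvature 0.25,
vmax 10 l0/s), exponential passive curve (exponent 4, strain 0.6), zero
pennation. All shape constants are per-muscle configurable; the shipped
f0/l0 table holds generic adult lower-limb values and is meant to be
overridden per subject via a YAML file. The passive term is included in
the achievable-force envelope by default (`include_passive` switches it
off); under the linear activation-scaling assumption the solved muscle
force is a·f\*, which is also what the cost functions normalize.

Physiological activation dynamics: `da/dt = (u − a)(t1·u + t2)` with
t2 = 1/T_fall and, in the default "literal" convention,
t1 = 1/(T_rise − t2). That expression mixes units (a time minus a rate);
the "standard" convention flag computes t1 = 1/T_rise − t2 instead, which
recovers the usual rise rate 1/T_rise at full excitation. Both give
positive rates for the default constants (T_rise 22 ms, T_fall 200 ms);
the literal form is the default for fidelity, the flag is the escape
hatch. Integration holds u piecewise-constant per step and applies the
exact exponential update, so constant-input closed forms are matched to
machine precision.

## Load sharing

Per sample, decision variables are the 15 activations and 3 motor
torques; the torque-balance constraint is *linear* because the motor
moment arms are unit vectors. Cost functions:

* CF1: δ·Σ(a_j f\*_j/f0_j)ⁿ + (1−δ)·Σ(T_o,k/T_o,k^max)ⁿ
* CF2: δ·Σ(−a_j f\*_j v_j)ⁿ + (1−δ)·Σ(T_o,k θ̇_k)ⁿ (powers; n = 2 squares
  the negative bases — no absolute-value variant)
* CF3: CF1 with the cycle maximum f_max,j as muscle normalizer
* CF4: minimax over all normalized muscle and motor terms, solved via the
  epigraph reformulation (minimize s subject to every term ≤ s)

Defaults δ = 0.5, n = 2, symmetric motor bounds ±40 N·m per joint (a
typical portable exoskeleton actuator peak).

The "actuators assist each other" requirement is implemented as per-joint
sign agreement T_FES,k·T_o,k ≥ 0. A strict-literal mode (product of the
two cost components ≤ 0) exists behind the `assistance="literal"` flag:
taken at face value it forces one actuator to zero at all times, which
contradicts every intended use, so it is not the default; `off` disables
the constraint entirely.

Solver: SLSQP with analytic gradients, linear equality jacobian, up to 3
deterministic starts (zeros, previous-sample warm start, box midpoint).
After each solve the motors re-absorb the (linear) equality exactly via
clipping to bounds, so converged residuals sit at machine precision, far
below the 1e-6·max(1, ‖T‖∞) tolerance. Ties are broken toward minimal
‖T_o‖ by a 1e-9-weighted secondary term, making solutions deterministic.
Infeasible demands are detected by a linear-program pre-pass and reported
with the achievable-torque gap; trajectory solves report every failing
sample index. A vectorized exhaustive grid oracle (≤ 3 muscle variables,
motors eliminated through the equality) provides the independent
correctness check.

Empirical note on the cost functions: on the synthetic trial the cycle
maxima f_max exceed f0 for every muscle (the eccentric branch of the
force–velocity curve pushes the envelope above isometric), so CF3's
normalizer is the larger one, muscle use is relatively cheaper than under
CF1, and CF3 produces the larger muscle contribution at the hip — the
ordering the method predicts from the normalizer comparison. Raising δ
(which multiplies the *muscle penalty*) empirically shifts torque toward
the motors on this trial; δ is therefore a motor-vs-muscle priority knob
whose direction should be checked on the instance at hand rather than
assumed.

## FES synthesis

Static blocks: the isometric recruitment curve S_u (0 below threshold
U_tr, linear to saturation U_sat, 1 above; defaults 20/40 mA, shared by
all muscles, per-muscle overridable) and the frequency-force sigmoid
S_f(f) = (k1−k2)/(1+e^{(f−f0)/R}) + k2 calibrated in closed form so that
S_f(0) = 0 and S_f(f_CF) = 1, with k2 = F_max/F_CF (default 1.2),
f_CF = 30 Hz, R = 15 Hz. The sigmoid's supremum is k2 > 1, so excitations
up to k2 are representable above the fusion frequency. The sigmoid pair
(k1, k2) and the linear-block pair are distinct constants that share
symbols in the source literature; the linear block uses (c1, c2) here to
keep them apart.

Linear block: c1·ä + c2·ȧ + a = e with c1 = T_e·T_rise/fall,
c2 = T_rise/fall + T_e. The rise/fall constant is chosen per sample by
whether the excitation drives activation up (e ≥ a), mirroring the
asymmetry of the physiological dynamics; the rule is configurable to a
fixed constant. Inversion uses first/second backward differences exactly;
the first two samples, which lack backward history, are filled by an
order-3 spline extrapolated from the first four interior values. An
optional zero-phase smoothing of the activation is off by default.

Profile construction clamps the required S_u to [0,1] (amplitude mode) or
the required S_f to the invertible range (0, k2) plus a 50 Hz command
ceiling (frequency mode), and sets a mask exactly where clamping occurred.
When a muscle is off (S_u = 0) the commanded intensity is reported as 0
rather than the mathematical inverse U_tr — no sub-threshold current is
commanded; a flag recovers the literal inverse. The forward model (static
blocks + RK4 integration of the linear block) is used as the independent
round-trip oracle: for activations bounded away from zero and saturation
and dt ≤ cycle/100, inversion followed by forward simulation recovers the
activation with RMS ≈ 2e-3 (tolerance 1e-2). Activations demanding
excitation outside [0, k2·S_u-image] — very fast decays, near-zero dwell —
are clamped and flagged rather than reproduced.

## Fatigue

Two capacity models (ψ ∈ (0,1] multiplies achievable force):

* Exponential, time-driven, muscle-independent:
  ψ(t) = e^{−C1·t−C2} + C3, defaults C1 = 0.02 1/s, C2 = 0.3, C3 = 0.2
  (≈ 80 % peak-force loss over 180 s; asymptote C3). Note ψ(0) ≈ 0.94,
  not 1: the model starts slightly sub-maximal. Implemented literally; a
  normalize-to-1-at-0 flag exists, off by default.
* Riener-type, activation-driven, per muscle:
  dψ/dt = (ψ_min − ψ)a/T_fat + (1 − ψ)(1 − a)/T_rec, integrated with the
  exact piecewise-constant-input update. Shipped constants (ψ_min = 0,
  T_fat = 18 s, T_rec = 76 s) are external-literature defaults, flagged
  for per-subject override; heavily stimulated muscles fatigue earlier
  and idle muscles recover.

Coupling into the re-planning: ψ weights the (n-th-powered) muscle cost
terms *and* scales the available muscle force in the constraint
(effective capacity ψ·f\*, so the solved muscle force is a·ψ·f\*); the
cost terms keep the unfatigued f\* as normalizer. Both couplings are
individually switchable, both on by default. Under this combination the
cost of muscle-produced torque grows as 1/ψ (n = 2), so as fatigue
progresses the optimizer raises activations (and thus stimulation) while
the FES torque share falls and the motor share rises — total torque is
unchanged. ψ is held constant within a gait cycle and updated between
cycles; for the exponential model only the cycles containing requested
snapshot times are solved (exact, since ψ there depends on time alone),
while the Riener model steps through cycles, optionally holding each
solved activation pattern for `riener_cycle_stride` cycles.

Fine print on the monotone share shift: at the hip and knee the per-phase
FES decline/motor growth holds to machine precision. At the ankle, whose
shares are two orders of magnitude smaller (~0.1 N·m), biarticular
gastrocnemius/hamstring coupling produces ~0.3 N·m non-monotone
redistributions between snapshots; the per-joint cycle-RMS FES share
still declines strictly at all three joints. Blanket per-phase
monotonicity across all joints is not a theorem of the coupled optimum.

## Numerical choices and degenerate inputs

* Trial files: CSV (17-significant-digit floats, bit-exact round trip) or
  an OpenSim-storage-style text dialect (`endheader`, declared
  nRows/nColumns honoured and checked).
* Residual tolerance 1e-6·max(1, ‖T‖∞); solver ftol 1e-12; calibration
  boundary conditions hold to 1e-12.
* Locked motors (zero-width bounds) contribute no cost term; a zero
  To_max on a *movable* motor is a configuration error.
* Empty trials, non-monotone time, unknown muscle columns, sub-threshold
  fixed intensities, non-calibratable sigmoid parameters and wrong-kind
  fatigue models all raise typed errors naming the offence.
* Problem sizes used by the shipped validation: 101-sample cycles for the
  full-trajectory and fatigue checks (the percent-of-cycle convention),
  21-sample cycles where only solver plumbing is exercised, 1e-3 grid
  resolution for the oracle comparisons — sizes at which each check's
  conclusion is already stable.

## Known limitations

* No ground contact, exoskeleton inertia, or human–device interaction
  forces; net torques are treated as human-only demands.
* No compliant tendon, pennation, EMG calibration, metabolic cost, or
  calcium-dynamics fatigue models; no muscle synergies.
* The real-time cooperative control loop is out of scope: the method is
  an off-line profile designer.
* All muscles share default recruitment thresholds; subject-specific
  measurement is expected for clinical use.
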