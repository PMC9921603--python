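# Methods

This note documents the model, the numerical and design choices, and what the
synthetic-data tests do and do not demonstrate.

## Model

### Activation dynamics

Raw EMG is conditioned offline with zero-phase (forward–backward) filters:
an order-5 Butterworth band-pass at 10–500 Hz, an order-5 Butterworth
band-stop at 48–52 Hz for the power line, rectification, and an order-4
zero-phase low-pass envelope at 6 Hz (configurable). The band-pass requires a
sampling rate above 1 kHz; trials whose channels already contain envelopes
(any rate) skip straight to normalization. The envelope is divided by the MVC
envelope maximum and clipped to [0, 1] — MVC is by definition the attainable
maximum, so a trial envelope exceeding it is treated as measurement headroom,
not signal. Muscle activation uses the exponential shape map
a = (e^{Au} − 1)/(e^A − 1) with A = −20. At this value the map is nearly
saturating (a ≈ 1 − e^{−20u}), which compresses the usable u range to about
[0, 0.15]; smaller |A| values are accepted by the same function, but −20 is
the default the rest of the package is calibrated around.

### Musculotendon units

Each muscle is a Hill-type unit: contractile element
F_CE = F_max·a·f(l_m)·g(v) with a Gaussian force–length factor of width w
around l_mopt and a hyperbolic force–velocity factor; a parallel element
combining an exponential-toe/linear spring (slack l_ms, linear onset l_mc,
toe scale k_ml, shape k_me, linear stiffness k_m) with viscous damping B_m·v_m;
and a tendon with the same toe/linear spring form (l_ts, l_tc, k_tl, k_te,
k_t). The toe coefficient is the ratio k_toe/k_shape — the only reading that
yields newtons from (N/m)/(1/m) and makes the slope at the slack length equal
k_toe. Fiber state evolves as M_m·v̇_m = F_SE − F_CE − F_PE, and the tendon
length is kinematically tied to fiber length and the instantaneous joint angle,
l_t = l_ms + l_ts + s·r_p·q − l_m, with moment-arm sign s = +1 for the
extensor and −1 for the flexor (a fixed reference angle would decouple the
musculotendon path from joint motion entirely, so the instantaneous angle is
used). Joint torque per muscle is F_SE·r_p.

Velocity conventions: v_m is the fiber lengthening rate dl_m/dt everywhere;
the force–velocity argument is the shortening rate −dl_m/dt, so the factor is
1 when isometric, 0 at v_max (clamped beyond), and on the eccentric side the
same hyperbola is clamped at 1.5 to avoid its pole — the standard lengthening
plateau.

### Passive joint, gravity, load

The passive joint torque is the double exponential
τ_p = k₁e^{−k₂(q−q₂)} − k₄e^{−k₅(q₁−q)} plus viscous damping −B_p·q̇. q₁ and
q₂ are curve-shape constants, not reachable angles; their identified ranges
extend past 2π and are validated only as finite and non-negative. Gravity
m·g·r_cm·sin(π/2 − q) is part of the model (`gravity_mode="paper"`, default)
even though the task is performed in the horizontal plane with the elbow on
the table; `"horizontal"` zeroes it. The pulled weight adds point-mass inertia
load_mass·load_arm² to the segment moment of inertia (lever arm defaults to
the forearm length); table friction is ignored, consistent with the task's
smooth-surface setup.

### Sign convention

With q = 0 at full extension and flexion positive, the net torque is
τ_J = τ_p + τ_d + τ_G + τ_AG − τ_ANT: the flexor (agonist) torque drives
flexion. The alternative assignment with the antagonist entering positively is
kept behind `sign_convention="paper_literal"`. The default is the only
assignment under which the unactivated system is dissipative — with it, total
mechanical energy (kinetic + passive-elastic) decreases monotonically under
zero activation, which the test suite asserts; the literal variant pumps
energy through the muscle-tendon coupling.

### Integration

Fixed-step RK4 (Euler available) at dt = 0.5 ms, with activation linearly
interpolated across the substeps of each output sample. The step is set by
the fastest mode — tendon stiffness ~6·10⁵ N/m against muscle mass ~0.4 kg
gives ω ≈ 1.2·10³ rad/s, so ω·dt ≈ 0.6 — and validated by self-convergence
(halving dt changes the final angle by far less than 0.1 %; the error decays
at least fourth order under halving). Fiber state starts at l_m = l_mopt with
v_m = 0; a static-equilibrium root solve is available via
`fiber_init="equilibrium"`. A guard aborts a run when |q| exceeds π (the
functional range ends at ~2.6 rad) or a tendon length turns negative; the
identification loop converts such runs into a penalty fitness of 10⁶.

## Identification

The 24 identifiable parameters are the 17 musculotendon values (one set
shared by both muscles — per-muscle parameterization would double-count
against the published 24-variable setup) plus the 7 passive-joint values.
Shipped bounds come from the published group ranges; a half/twice preset
around user-supplied literature values is also provided. Three rows of the
published range table are misprinted (mean values inconsistent with their own
min/max columns); the bounds keep the min/max columns, which are the
physically plausible ones (B_m ~ 10² N·s/m, M_m ~ 0.4 kg, v_max ~ 1 m/s).
The published midpoint of l_ms exceeds that of l_mc, which the piecewise
parallel spring forbids, so the default synthetic ground truth clips l_ms
down to l_mc.

The fitness is the trapezoidal integral of |q_goni − q| over the trial,
evaluated in degrees (deg·s), a bounded-below repair of the signed-integral
form that a minimizer requires. GA operators: roulette-wheel selection with
minimization weights 1/(F + 10⁻¹²); scattered (uniform-mask) crossover;
Gaussian mutation with per-gene σ = 0.1 × bound range, truncated to the
bounds. Per generation at population 20: 14 crossover children, 2 elites,
4 mutants. Termination: best-fitness improvement ≤ 10⁻⁶ for 20 consecutive
generations, or the generation cap (200 by default; the desk-scale study uses
100). Because the ordering constraints l_ms ≤ l_mc and l_ts ≤ l_tc carve out
only a few percent of the bounds box, initial individuals are
rejection-sampled to the feasible region (uniform on that region); children
that become infeasible through crossover or mutation receive the penalty
fitness instead, preserving the specified operator semantics.

## Stiffness estimation

RLS in covariance form on τ_J = Φ(q)·Π with Φ = (1, q, q²), initialized at
Π = 0, P = 0.01·I (a cubic regressor and an exponential-forgetting variant are
available but off by default). The three-term regressor honors the printed
3-vector initialization of the recursion. Stiffness is reported as the
negative torque gradient −(π₂ + 2π₃q) in N·m/rad, the physically meaningful
quantity; the literal −Φᵀ·Π (which has torque units) is preserved behind
`mode="paper_literal"` for comparison. Note that P₀ = 0.01·I is a strong
ridge prior: on a 500-sample stream the coefficient estimates still carry an
O(1) prior bias, so exact-recovery tests use a diffuse prior (P₀ = 10⁸·I),
under which RLS coincides with batch least squares to below 10⁻⁸.

## Verification and scales

DTW uses absolute-difference local cost and the symmetric step pattern with
no window; the optimal accumulated cost is divided by the reference-series
length ("average deviation", configurable to path-length normalization).
Deviations are also expressed as percentages of the 150° functional elbow
range. The sensitivity table perturbs each identified parameter by ±10/20/30 %,
re-simulates, re-estimates stiffness and reports the DTW average deviation of
the perturbed stiffness trace from baseline; infeasible or divergent
perturbations are flagged rather than scored.

Repetitions are segmented by the metronome period 2·60/tempo s per
flexion+extension cycle (an angle-onset detector is the alternative; see
below). Segments are resampled to a 101-point 0–100 % phase grid for
mean ± std movement patterns. The per-repetition summary is the trapezoidal
area under the stiffness signal over the cycle; per-condition summaries (mean
over repetitions, mean across subjects; medians optional) feed the two
functional scales, a·tempo^b (fit in log–log-initialized nonlinear least
squares) and a·e^{b·weight} (semilog-initialized). Both fits recover
generating coefficients exactly on noiseless model data, which is the basis
of the scale-recovery acceptance checks.

## Synthetic data

The generator emulates the paced protocol: per cycle, a raised-cosine flexor
burst over the flexion half and a shorter extensor burst early in the
extension half (40 % of the half-cycle), over a constant co-contraction floor
of 0.05. Peak flexor activation is 0.40·(tempo/30)^0.7·(1 + 0.35·load),
capped at 0.90, with the extensor at 0.25 of the flexor — chosen once so
that, across every protocol condition (15–60 bpm × 0–1 kg), the simulated
angle spans a realistic 68–116° of flexion and never leaves [−5°, 155°].
The extensor burst is truncated because the model has no hard stop at full
extension (chest/table contact is not modelled): the return movement hands
over to the passive structures before the joint would hyperextend. For the
same reason the joint drifts back toward its passive equilibrium (~40°)
during the rest part of each cycle instead of waiting at 0°; consequently the
angle-onset segmentation method places cycle boundaries at the pre-burst
minimum, not at the metronome beat, and its exact-onset behavior is tested on
rest-at-baseline signals.

Measured channels are the simulated angle plus Gaussian goniometer noise
(0.5° std) and the generating activations pushed through the inverse
activation map, scaled by the MVC reference, with 5 % multiplicative envelope
noise — instrument-grade figures chosen as generator defaults, so that with
zero noise the processing chain recovers the generating activations to float
precision. Default ground truth: published-range midpoints (with the l_ms
clip above); default segment properties m = 1.5 kg, r_cm = 0.18 m,
M = 0.065 kg·m², r_p = 0.035 m, load arm 0.26 m — anthropometric values for
an adult forearm–hand segment.

What passing synthetic tests shows: that the estimator chain is internally
consistent — data generated by the model class is recovered by the model
class under realistic noise. What it does not show: robustness to model
mismatch in real recordings (electrode artifacts, fatigue, tremor,
co-contraction strategies outside the burst family, table friction, soft-
tissue moment-arm variation), none of which the generator emulates.

## Desk-scale study

`elbowstiff.study.run_identification_study` fixes the evaluation used by the
acceptance tooling: a 4-movement training trial at 30 bpm / 0.5 kg sampled at
100 Hz, GA identification at population 20 with a 100-generation cap, and
held-out evaluation at 60 bpm / 0.5 kg and 30 bpm / 1 kg. These sizes keep a
full study within tens of seconds on one CPU while preserving the protocol
structure; all randomness derives from a single seed via a seed sequence.
Typical outcomes: training DTW deviation 0.3–0.4 % of range, held-out at most
~1 %.

## Known limitations

- Single hinge joint; no wrist/shoulder coupling, no table contact or
  friction, no pennation, no activation–deactivation lag (the activation map
  is static), no history-dependent force.
- The GA is the plain published operator set; no surrogate models or
  restarts. With 2 000 evaluations it matches trajectories well but does not
  claim unique parameter recovery — most tendon-side parameters are nearly
  unidentifiable from angle data alone (the sensitivity table makes this
  visible), so identified vectors are task-calibrated models, not tissue
  measurements.
- Stiffness from torque–angle regression conflates inertial, viscous and
  elastic contributions within each cycle; it is a functional summary
  comparable across conditions, not a perturbation-validated impedance.
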