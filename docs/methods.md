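# Methods

This note documents the models implemented in `gaitbench`, their parameter
defaults and units, the numerical choices, what the synthetic generators do
and do not emulate, and the known limitations.

## Muscle–tendon model

Each muscle–tendon unit (MTU) is a massless Hill-type fiber in series with an
elastic tendon, evaluated under *prescribed* MTU kinematics (no skeletal
dynamics are integrated anywhere in the package).

**Sign conventions** (fixed once, used everywhere): fiber velocity is
lengthening-positive; fiber power `p = −F_fiber · v_fiber` is
shortening-positive, so concentric work is positive work.

**Activation dynamics.** First-order excitation–activation coupling

```
da/dt = (e − a) · (e/τ_act + (1 − e)/τ_deact)
```

with `τ_act = 0.015 s`, `τ_deact = 0.060 s` by default (both per-muscle
configurable). The effective rate constant blends activation and
deactivation time scales with the excitation level, so onset is faster than
decay, `e = a` is a fixed point, and any trajectory started in [0, 1]
remains in [0, 1]. The integrator takes exact exponential steps per interval
(the ODE is linear in `a` for the midpoint-frozen excitation), which is
unconditionally stable.

**Characteristic curves.** The curve forms are configurable via `CurveSet`;
the defaults are:

* *active force–length*: a two-Gaussian sum centered at the optimum,
  `f_act(l̃) = 0.85·exp(−(l̃−1)²/0.45) + 0.15·exp(−(l̃−1)²/0.09)`.
  Centering all Gaussians at `l̃ = 1` makes the peak exactly 1 at exactly
  the optimal length — an anchor the rest of the package (isokinetic
  protocol, oracle tests) relies on. The widely used tri-Gaussian
  coefficient set from the muscle-modeling literature is shipped as
  `TRI_GAUSSIAN_FL` for users who prefer it; its peak is ≈ 1 near, but not
  exactly at, `l̃ = 1`, which is why it is not the default.
* *passive force–length*: exponential toe curve
  `(exp(k_pe(l̃−1)/ε₀) − 1)/(exp(k_pe) − 1)` for `l̃ > 1`, zero below, with
  `k_pe = 4`, `ε₀ = 0.6`.
* *force–velocity*: Hill hyperbola `(1 + ṽ)/(1 − ṽ/a_f)` on the concentric
  side (`a_f = 0.25`; exactly 0 at `ṽ = −1`, exactly 1 at `ṽ = 0`), joined
  C¹-continuously to a saturating eccentric branch with plateau
  `f_ecc = 1.5`.
* *tendon*: exponential `(exp(k_T(l̃_T−1)/ε_iso) − 1)/(exp(k_T) − 1)` above
  slack length, zero at or below; `ε_iso = 0.049` (strain at which
  normalized force reaches 1), shape `k_T = 3`. Its closed-form strain-energy
  integral is exposed (`tendon_strain_energy`) so cyclic energy audits can
  use the exact state function.

`v_max` defaults to 10 optimal fiber lengths/s. Pennation uses the
constant-thickness model: width `w = l_opt·sin(α_opt)` is conserved, so
`cos α = √(l_f² − w²)/l_f` and the along-tendon fiber velocity is
`v_f/cos α`.

**Fiber–tendon equilibrium.** In compliant mode the solver brackets and
root-finds (Brent, xtol 1e-12) the residual `F_T − F_f·cos α` over
normalized fiber length; a cold solve scans 120 points from the shortest
feasible fiber and takes the first sign change (deterministic smallest-root
tie-break; the residual is monotone for physiological inputs, so this is
also the unique root), while trajectory solves warm-start from the previous
sample. Residuals are ≤ 1e-8 of `F_iso` (typically ≤ 1e-11). Rigid mode
pins the tendon at slack length and evaluates the fiber from geometry.

*Velocity indeterminacy.* At a single instant, `(l_mtu, v_mtu, a)` do not
determine the fiber/tendon velocity split — fiber length is a state of the
true contraction dynamics. Pointwise solves therefore evaluate the
force–velocity curve at the rigid-partition velocity `v_mtu·cos α` (exact
when `v_mtu = 0`, e.g. the isometric oracle case). The trajectory solver
then *recomputes* fiber velocity by differentiating the solved fiber-length
series — spectrally (FFT) for periodic uniform grids, second-order finite
differences otherwise — and reports fiber power from that refined velocity.
Because the force balance holds at every sample and tendon strain energy is
a state function, this makes the cyclic identity

```
W_mtu = W_fiber + ΔE_tendon,   ΔE_tendon = 0 over a closed cycle
```

hold to discretization accuracy (∼1e-11 of `F_iso·l_opt` on the test
trajectories, against a tolerance of 1e-6).

## Metabolic energy models

**Heat-rate model.** Instantaneous metabolic power is the sum of activation
heat, maintenance heat, shortening/lengthening heat, and fiber mechanical
work rate. With recruitment weights `u_slow = f_slow·sin(π/2·e)`,
`u_fast = (1 − f_slow)(1 − cos(π/2·e))`:

```
Ḣ_act   = m · φ · (u_slow·A_slow + u_fast·A_fast)
Ḣ_maint = m · g(l̃) · (u_slow·M_slow + u_fast·M_fast)
Ḣ_sl    = −α·v_fiber ;  α = 0.16·F_iso(a, l̃) + 0.18·F_ce   (shortening)
                        α = 0.157·F_ce                      (lengthening)
ẇ       = p_fiber
```

Defaults (the published coefficient set of the cited heat-rate model):
`A_slow/A_fast = 40/133 W/kg`, `M_slow/M_fast = 74/111 W/kg`; `g(l̃)` is the
piecewise-linear maintenance modulation through (0, 0.5), (0.5, 0.5),
(1, 1), (1.5, 0); muscle mass `m = F_iso/σ·ρ·l_opt` with density
`ρ = 1058.7 kg/m³` and specific tension `σ = 0.25 MPa` when no mass is
given. The stimulation-duration decay factor `φ` (floor 0.06, time constant
10 s) and a per-muscle basal rate exist as config switches but default to
*off* — published implementations differ on both, so neither is silently
assumed; coefficient sets load from YAML/JSON with field validation.

*Positivity.* The signed component sum can go negative at fast lengthening
(negative work rate outweighs the heats). Two clamping modes are provided:
`exact` (hard `max(·, 0)`, the analysis default) and `smooth`
(`0.5·(x + √(x² + b²))`, width `b = 10 W`), which is strictly positive and
differentiable as required by gradient-based optimal control. A tanh-based
positive part was considered and rejected: `0.5·x·(1 + tanh(x/b))` is
negative for negative inputs, which breaks efficiency ratios.

**Efficiency-based model.** `Ė = p⁺/0.25 + p⁻/(−1.2)`: concentric power
charged at 25 % efficiency and eccentric power at −120 %, so dissipating
mechanical energy still costs positive metabolic energy. Nonnegative,
piecewise linear, zero only at zero power; it has no isometric cost, which
is its defining (and deliberately unrealistic) simplification.

Stride energies are trapezoidal integrals of the rate series on the trial's
native grid; net metabolic energy subtracts `basal_rate · stride_time`
(whole-body basal, default 0).

## Isokinetic efficiency analysis

The maximal-efficiency protocol clamps the fiber state directly — `a = 1`,
`l̃ = 1`, velocity prescribed, no tendon and no activation dynamics — because
that is what an isokinetic single-fiber protocol controls; inventing a
tendon/stimulation protocol would add unmodeled confounds. Efficiency is
`p_fiber/Ė_total` on a default grid of 2001 points over `ṽ ∈ [−0.999, 0.999]`
(singular endpoints excluded), with extrema sharpened by two local
refinement passes at 10× resolution (argmax stability against grid
placement). Efficiency is defined as exactly 0 wherever `p_fiber = 0`
(covers the efficiency-based model's `0/0` at `ṽ = 0`); a zero metabolic
rate at nonzero power raises an explicit error.

The sweep's default energy model uses the *smooth* positivity mode: with the
hard clamp, the total rate is exactly zero at fast lengthening and the
efficiency ratio would be undefined there. The smoothing width makes the
eccentric extremum grid- and width-sensitive (it occurs where the total rate
is nearly zero); eccentric minima should be read as order-of-magnitude
statements — they are large negative numbers (−10³…−10⁶ depending on grid
and smoothing), meaning dissipating work while fully active is metabolically
very expensive. Under the default coefficients, maximal concentric
efficiency rises monotonically with the slow-twitch fraction (slow fibers
have lower heat constants), spanning roughly 0.37–0.48 over
`f_slow ∈ [0, 1]` — far above the 0.2–0.3 measured on isolated fibers,
which is the point of the audit.

## Stride accounting and the cost function

Fiber work splits as trapezoidal integrals of `max(p, 0)` / `min(p, 0)`;
cost of transport is `E/(m·v·T)` (J/kg/m), reported on net metabolic energy
(equal to total when basal is 0 — both are accessible, since conventions
differ between labs). Activation cost is the time-averaged mean activation
over a muscle subset; volume weighting uses an external volume table when
given and otherwise the proxy `F_iso·l_opt` (proportional to volume at fixed
specific tension — a proxy, not measured volumes). The cost function is

```
J = (1/d) Σᵢ wᵢ ∫ ‖·‖₂² dt
```

with the instantaneous squared 2-norm taken across the vector channel
(muscles, coordinates, motors) and `d` the distance traveled per gait cycle
(`speed · stride_time`; configurable to a plain duration). Passive joint
torques use a symmetric double-exponential limit stiffness
`−k(e^{s(q−q_hi)} − e^{−s(q−q_lo)})` plus linear damping `−c·q̇` (defaults
`k = 2 N·m`, `s = 5 rad⁻¹`, limits ±1 rad, `c = 0.1 N·m·s/rad`, per-joint
configurable); damper dissipation is `∫c·q̇² dt` and contact dissipation the
net negative contact work `−∫min(ΣF·v, 0) dt`, reported positive.

## Normalization and comparison

Frequencies are normalized by `√(g/l)` — the text this analysis follows
prints "g/l", but only the square root is dimensionally a frequency, so the
root is used and the discrepancy documented here. Moments normalize by
`mgl`, forces by `mg`, powers by `m·g^1.5·l^0.5`; the reference model is
62 kg and 1.70 m stature with leg length `0.53 × stature` (ratio
configurable — the model's actual leg length is not published). Deltas
subtract a global reference condition (level walking at 1.1 m/s in the
intended use) or, for added-mass analyses, the zero-mass condition at the
same speed. Agreement statistics come from OLS of simulated on experimental
deltas, intercept included by default (a through-origin option exists since
"slope" is read as over/underestimation of changes); R² is the fit's
explained variance, while the primary RMSE is computed on paired sim−exp
differences (the fit-residual RMSE is also returned — the convention is
ambiguous in the literature, so both are exported and named).

## Interventions

World frame: x forward, y up, z right; positive grade = uphill. Added mass
is a true point mass (no own inertia — no extent is specified for attached
loads): mass adds, COM is the mass-weighted mean, and inertia about the new
COM follows from parallel-axis transfer of both bodies, making attachments
associative and order-independent. Slope rotates gravity by
`θ = atan(grade/100)` about z, preserving magnitude. Crouch ceilings
(fraction of unconstrained pelvis height, e.g. 0.93) and imposed speeds are
validated records only — applying them belongs to an optimal-control solver,
which is out of scope here.

## Synthetic data

The generators produce the three data shapes the pipeline consumes, seeded
and bit-for-bit reproducible (one root seed expanded through spawn keys:
0 = muscles, 1 = trial, 2 = conditions).

* *Muscle sets*: `F_iso` log-uniform on [100, 5000] N, `l_opt` uniform on
  [5, 15] cm, tendon slack 1.2–2.5 × `l_opt`, pennation ≤ 0.35 rad,
  `f_slow ~ Beta(2, 2)`. Defaults sized to the 92-muscle lower-limb scale.
* *Trials*: default 92 muscles, 1.1 s stride at 1.3 m/s, 101 samples, 62 kg
  body. MTU lengths are 3-harmonic Fourier series around an operating point
  just above tendon slack with the fiber near optimum (equilibrium feasible
  by construction); excitations are smooth periodic signals in [0, 1];
  activations are integrated to a periodic orbit (3 warm-up cycles — the
  per-cycle contraction factor makes the periodicity gap < 1e-9); fiber
  states come from the equilibrium solver; joint channels are consistent
  Fourier series (q̇, q̈ analytic); contact channels follow a stance-phase
  (60 %) force bump with small downward contact velocities.
* *Condition datasets*: experimental deltas drawn uniformly (default
  −50…400 W around a 300 W baseline), simulated deltas
  `intercept + slope·Δ_exp + N(0, σ)`. The noise sits on the simulated side
  — the response of the comparison regression — so the known slope is
  recovered without attenuation bias; putting noise on the regressor would
  bias the slope low by construction, which would defeat the recovery test.

What the generators do **not** emulate: muscle redundancy and co-contraction
patterns, realistic joint-angle waveforms, moment arms or any coupling
between the joint and muscle channels, ground-reaction dynamics, or
inter-subject variability. Passing tests on synthetic trials therefore
demonstrates the correctness of the accounting and solvers, not the
biomechanical realism of any simulated gait.

## Problem sizes and determinism

Test and demonstration runs use down-scaled sizes chosen as the package's
own defaults for fast iteration: 4–8 muscle trials at 81–101 samples,
401–2001-point sweep grids, 100-condition comparisons, 200-case property
sweeps. All randomness flows through explicit seeds; `hypothesis` suites run
derandomized. The acceptance script (`scripts/acceptance.py`) recomputes the
efficiency-based model's definitional stride efficiencies from freshly drawn
strictly-concentric and strictly-eccentric power trajectories (401 samples)
— these are exact consequences of the model definition, so their values are
seed-independent while every input series is not.

## Known limitations

* No skeletal dynamics, muscle paths, or moment arms: the package consumes
  MTU kinematics, it does not produce them.
* The pointwise velocity partition is an approximation; only trajectory-level
  solves (with velocity refinement) satisfy the cyclic energy balance to
  high accuracy.
* Eccentric efficiency extrema depend on the sweep grid and smoothing width
  near the zero-crossing of the clamped rate; treat them as
  order-of-magnitude outputs.
* The heat-rate model's stimulation-duration decay is implemented but
  unvalidated against any reference implementation and off by default.
* The Umberger-family energy models are not implemented.
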