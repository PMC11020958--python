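# Methods

## Model and assumptions

The walker is a point mass `m` on a massless leg of variable length that
pivots about the active ground contact; gravity `g` acts downward, walking
is in the positive `x` direction, the ground is at `y = 0`.  Because the
leg is massless, the pendular torque `M` about the contact is equivalent to
a shear force `S = M/l` at the point mass, perpendicular to the axial leg
force `F`.  Given the CoM trajectory and its derivatives, `F` and `S`
follow algebraically from Newton's second law (no optimization, no muscle
model), which is what makes the method usable with a single kinematic
sensor.

Key assumptions:

* **Single stance.**  Exactly one leg bears load at any instant; the
  swing→stance hand-over is instantaneous, at the minimum of the CoM
  height.  Real double stance is not modelled explicitly, but because the
  model is kinematics-driven it still produces two simultaneous force
  channels (`F` along the leg, `S` across it) whose powers stand in for the
  two legs' combined action during that phase.
* **Foot placement at midstance.**  The contact point of a stance period is
  the CoM's forward position at the step's bounding height maximum, at
  ground level.  A step and its length `d` run midstance → midstance.
* **Planar motion.**  Lateral CoM motion is ignored (sagittal-plane model).
* **Periodicity (for the work balance).**  Over a steady step the net leg
  work is zero, so positive and negative work per step are equal; the
  energetics module checks rather than assumes this.

Per-sample invariants used as internal checks: the polar round trip
`(l sin φ, l cos φ) = (x_rel, y)`; the ground-reaction identity
`Fx = m ẍ`, `Fy = m (ÿ + g)`; and the energy-rate identity
`P_F + P_M = m (ẋ ẍ + ẏ (ÿ + g))`, which holds algebraically for any
derivative fields and to machine precision on the analytic gaits.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `m` | — (required) | kg | body mass; cancels in `C` for prescribed kinematics |
| `g` | 9.81 | m/s² | gravitational field strength |
| `b` | 0.2 | — | weight of negative muscle work in the energy tally, after the classical eccentric-work measurements |
| `d` | 0.77 | m | synthetic step length |
| `l0` | 1.07 | m | maximum leg length; switch geometry `φ₀ = arcsin(d/2/l0)`, `h = √(l0² − (d/2)²)` |
| `v0` | 1.4 | m/s | step-average forward speed (not the midstance speed) |
| `a` | 0.02 | m | sinusoidal half-excursion |
| filter pass/stop | 6 / 10 | Hz | low-pass band edges for measured data |
| `min_prominence` | 2 | mm | height-peak prominence for step detection |
| `min_separation` | 0.3 | s | minimum spacing between midstances |

The synthetic defaults describe a tall adult (1.84 m, 94 kg) walking at
self-selected speed; they are shared across all three gaits so their costs
are comparable.

## Synthetic gaits

* **Level**: `y ≡ h`, `x = v0 t`.  The mean height convention for all
  smooth gaits is that the leg reaches exactly `l0` at the switch, i.e. the
  height *minimum* equals `h`.  Positive work per step has the closed form
  `2 m g h ln(l0/h)` (derived by integrating `[P_F]⁺ = m g v0 sinφ cosφ`
  over the half step and doubling by symmetry), used as an independent
  oracle for the numerical pipeline.
* **Sinusoidal**: `y = h + a + a cos(2π x_rel/d)` at constant forward
  speed; maxima at midstances, minimum `h` at the switches; the `a → 0`
  limit is the level gait exactly.
* **Pendular**: rigid leg, arcs of radius `l0` about contacts spaced `d`.
  Energy conservation along an arc gives
  `v(φ)² = v_mid² + 2 g l0 (1 − cos φ)`; the half-step duration is the
  quadrature `t_half = l0 ∫₀^{φ₀} dφ / v(φ)` and bisection on `v_mid`
  enforces `d / t_step = v0`.  Interpreting `v0` as the *average* speed is
  essential — using it as the midstance speed does not reproduce the
  reference collision loss.  Samples follow the pendulum time law
  `φ̈ = (g/l0) sin φ`, integrated once per half arc (DOP853,
  rtol 1e−11) and mapped to the grid by the odd symmetry of `φ(t)`; the
  quadrature provides an independent cross-check on the ODE route.  The
  heel-strike collision (pre-impact velocity projected perpendicular to the
  new leg) loses `E = ½ m v_hs² sin²(2φ₀)`; the matching push-off restores
  it, so the step ledger charges `E` once as positive and once as
  b-weighted negative work.  Power along the arcs is identically zero.

All generators attach exact analytic derivatives, and the pipeline uses
them when present (a switch forces the numerical path for convergence
studies).  Records carry half a step of margin on each side so every
midstance is interior.

## Numerical choices

* **Filter.**  Only the band edges are treated as normative; the
  realization is a minimum-order Butterworth (scipy `buttord`/`butter`,
  second-order sections) applied forward–backward (`sosfiltfilt`, reflected
  padding).  The dB budget is split across the two passes (0.5 dB ripple,
  20 dB attenuation per pass), so the zero-phase response meets ≤1 dB in
  the pass band and ≥40 dB in the stop band.  For measured data the chain
  is filter → differentiate → filter → differentiate → filter, i.e. each
  differentiation stage is re-filtered, and the filtered positions are the
  ones segmented and analyzed.
* **Differentiation.**  Central differences on the uniform grid
  (`np.gradient`), first-order one-sided at the record endpoints; exact for
  quadratics on interior samples.
* **Step detection.**  `scipy.signal.find_peaks` on the conditioned height
  with prominence and spacing thresholds; plateaus resolve to their first
  sample.  Midstance times are then refined to sub-sample precision by a
  least-squares parabola over ±⅓ of the minimum separation around the
  discrete maximum, and the contact abscissa interpolates `x` there.  The
  refinement is exact on noiseless symmetric peaks and removes the
  whole-sample quantization that otherwise dominates step-length error
  under marker noise; `refine=False` restores plain grid extrema.  Sample
  indices (used for the work integrals) always stay on the grid.
* **Work integrals.**  Per-sample clipping `[P]± = max(±P, 0)` followed by
  trapezoidal integration; no sub-sample zero-crossing interpolation (the
  omitted slivers are second order in the time step).  Each step is
  integrated as two phases split at the switch sample, which is evaluated
  under *both* legs — the old leg up to the switch instant, the new one
  from it — so the hand-over discontinuity is not smeared across a sample
  interval.  At a 1 ms time step the level-gait work matches its closed
  form to <0.1%.
* **Pendular cusp caveat.**  The cusp velocity is genuinely two-valued and
  the trajectory container stores one value (the new arc's).  The old leg's
  phase integral therefore picks up a spurious ~0.26 J at the cusp sample
  (O(Δt); +0.4% on the pendular C at 1 kHz).  The pendular work ledger is
  analytic anyway (`E_impact`), so this residual only shows up as a small
  nonzero `W±` on an otherwise workless gait.
* **Degenerate inputs.**  Constant-height records have no height extrema
  and cannot be segmented from `y`; generator-provided segments (or a
  sidecar file via the CLI) cover that case.  Trajectories must be
  uniformly sampled (1e−9 relative tolerance), at least 3 samples, with
  `y > 0` throughout.

## What the synthetic generators do and do not emulate

They reproduce the geometry and energetics of idealized steady gaits —
exact periodicity, identical steps, known contacts — plus optional additive
white Gaussian position noise (`add_noise`), which emulates marker noise
amplitude but not its temporal correlation, soft-tissue artifact, gaps, or
step-to-step physiological variability.  Passing the noisy-pipeline tests
therefore demonstrates robustness of the numerics (filtering,
differentiation, event detection, integration) to sensor-grade noise, not
validity of the model for pathological gait.  Real recordings also start
and end mid-step; everything outside the first/last detected midstance is
discarded.

## Design choices where the design was open

* The step-average-speed interpretation of `v0` for the pendular solve
  (see above).
* The sinusoid's mean height (minimum at `h`): matches the level-gait
  geometry at `a = 0` and keeps the switch leg length at `l0` across all
  three gaits.
* The switch sample belongs to the new stance leg (half-open step
  intervals), so per-step quantities partition the record exactly.
* `g = 9.81 m/s²` as the default field strength.
* Problem sizes: 4 steps at 1 kHz for reference computations (work
  integrals converged well past the reported precision), 200 Hz when
  emulating motion capture.

## Known limitations

* Sagittal-plane only; no lateral work.
* No force-plate ingestion: the model's ground-reaction forces are an
  output (`Fx = m ẍ`, `Fy = m (ÿ + g)`), not validated against measured
  plates inside this package.
* Double stance is represented only through the two force channels of the
  single-stance model; individual-leg forces during overlap are not
  resolved.
* The cost `C` is mechanical, not metabolic; the negative-work weight `b`
  is a fixed constant, not fitted.
* The vertical-excursion sensitivity of `C` is non-monotone (minimum near
  `a ≈ 0.02 m` at the reference parameters), so sensitivity statements
  depend on which side of the optimum a gait sits.
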