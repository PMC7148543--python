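# Methods

This note documents the model implemented by `lvloop`, the unit and
numerical conventions, the design choices made where the formulation was
genuinely open, and the known limitations of the parameter set shipped in
the presets.

## Model structure

The state vector concatenates three subsystems:

| block | states | role |
|---|---|---|
| sarcomere | v_c, ε_c, τ_c, k_c | contractile-element mechanics and active tension |
| electric | p, q | paced relaxation oscillator, source of the chemical drive u = α_u q |
| circulation | V, m, n (+ F_a, P_R, P_S) | ventricular volume, aortic pressure, pump flow (+ systemic loop) |

giving 9 ODEs for the *basic* circulation (constant atrial pressure
P_R and Windkessel relaxation of the aortic pressure m toward a constant
m₀) and 12 for the *extended* one (dynamic aortic flow, atrial and
arterial pressures).  All switching — valve diodes, activation gating
Θ(u), stretch gating Θ(V−V₀), the pump suction penalty — uses a hard
Heaviside step with the convention Θ(0) = 0, so every switched term
vanishes exactly on its switching surface.

Assumptions worth keeping in mind:

* The ventricle is a single lumped chamber; the contractile element is a
  single representative sarcomere, not a spatial population.
* Chemical activity is the scalar u; there is no calcium-cycling detail.
* The pacing is a fixed 1 Hz sinusoidal forcing of amplitude 10 (a resting
  heart rate); the frequency is configurable but every preset uses 1 Hz.
* Valves are ideal diodes in series with constant resistances; no valve
  inertia or regurgitation (the *pump* may carry backward flow, the valves
  may not).

## Units

Stress-valued quantities (τ_c, k_c, σ_P and the parameters σ₀, k₀, k₂) are
carried internally in kPa.  A single conversion constant, 7.5006 mmHg/kPa,
is applied where stresses become pressures, inside the map

    P_V = c · γ (V₀/V)^α [d₀ τ_c + σ_P],   c = 7.5006 mmHg/kPa.

This regime is forced by the equations themselves: if the stress numbers
were fed to the pressure law without conversion, the passive pressure
γ(V₀/V)^α k₂(V/V₀−1) could never reach the 9 mmHg filling pressure at any
physiological volume for α ≥ 1, and for α = ½ would clamp filling only
near 2.8·V₀, where the length–tension factor extinguishes contraction
entirely — the simulated ventricle fills and never beats.  With the
conversion, diastole terminates near 1.15·V₀ and the system settles into a
1 Hz limit cycle within two or three beats.  The mechano-electric coupling
μ₁τ_c uses τ_c in kPa, matching μ₁'s unit of kPa⁻¹.

Volumes are mL, pressures mmHg, flows mL/s, time s.  Pump speed ω is in
rpm (a rotation rate, not an angular frequency) and enters the pump head
as β ω² with β = 9.9025×10⁻⁷ mmHg/rpm² — the standard head coefficient of
the axial-pump model family this circulation derives from; it is a
configurable assumption, validated here only through the suction-onset
behaviour it produces (onset at ≈11.6 krpm on the slow ramp).

## The volume exponent α

The geometry factor (V₀/V)^α interpolates between two defensible readings
of a thin-walled chamber law: α = ½ for a constant-height cylinder whose
radius scales as √V (wall tension ∝ stress·thickness/radius), and α = 1
for a direct V₀/V ratio.  Both were calibrated against the control-case
elastance extrema; α = 1 reproduces the end-systolic stiffness
(E_max ≈ 2.08 mmHg/mL, and ESPVR slope 2.08 mmHg/mL across the afterload
sweep) distinctly better than α = ½ (E_max ≈ 2.7) and is the default.
`pv_volume_exponent` remains a config field so the cylindrical reading can
be selected.

## Default parameters (control presets)

χ = 100 s⁻¹, ω₀ = 100 s⁻¹, a = 100, b = 6000, α_l = 10, σ₀ = 240 kPa,
k₀ = 120 kPa, β₀ = 20, k₁ = 0.002, k₂ = 14 kPa, γ = 0.6, V₀ = 144/1.5 mL
(stored as the exact ratio, 96 mL); μ₁ = 0.0024 kPa⁻¹, μ₂ = 0,
α_u = 5 s⁻¹; R_A = 0.001, R_M = 0.005, R_S = 0.5, R_C = 0.0398 mmHg·s/mL,
C_R = 4.4, C_S = 1.33, C_A = 0.08 mL/mmHg, L_S = 0.0005 mmHg·s²/mL,
m₀ = 70 mmHg, P_R = 9 mmHg; pump L* = 0.0472 mmHg·s²/mL, R* base
0.3061 mmHg·s/mL with the suction penalty 3.5·(1 mmHg − P_V) added below
P_V = 1 mmHg.  The dilated-cardiomyopathy presets change only
k₂ = 40 kPa, V₀ = 144 mL, γ = 0.45: an enlarged, stiffer, weaker chamber.

μ₁ = 0.0024 gives the tension cycle an active (u > 0) phase of ≈0.45 s per
1 s beat — a physiological systolic fraction; μ₂ is zero in every preset
and nonzero values, while reachable through config, are unvalidated.

Degenerate inputs: k₁ → 0 switches the passive stress to its analytic
linear limit k₂(V/V₀ − 1) instead of dividing by zero; V ≤ 0 anywhere
raises a ventricular-collapse error; a volume floor (default 10⁻³ mL)
aborts integration, distinguishing numerical collapse from the suction
regime, where negative ventricular *pressure* is a valid model output.

## Integration

The right-hand side is non-smooth (switches) and stiff (the aortic-flow
relaxation rate R_C/L_S ≈ 80 s⁻¹, valve-open aortic coupling
1/(C_A R_A) = 12 500 s⁻¹, microscale frequency ω₀² = 10⁴ s⁻²).  The
default integrator is LSODA with rtol 10⁻⁷, atol 10⁻⁹ and max_step 10 ms,
so no switching surface is overstepped by more than a fraction of a beat;
a logistic smoothing of the step (width `theta_eps`) is available as an
escape hatch but defaults to off — the hard-switch model as stated.
Correct switch handling is verified by an independent fixed-step
classical RK4 integrator at dt = 10⁻⁴ s: on the 20 s control run the two
agree to ≈10⁻⁶ relative, and to better than 10⁻² on a pump-assisted
failing-heart run.  Trajectories are sampled on a 1 ms output grid;
derived signals (P_V, d₀, σ_P, u, ω) are recomputed from the stored states
rather than stored separately.  Runs are bit-reproducible for a fixed
scenario, and every output embeds a content hash of the scenario.

Unstated initial values default to rest (zeros for the microscale,
electric and pump states), m(0) = m₀, V(0) = 0.5 V₀ (basic) or 0.9 V₀
(extended), and F_a(0) = 90 mL/s, P_R(0) = 10 mmHg, P_S(0) = 70 mmHg for
the extended variant; all are overridable.  Steady-state analysis discards
the first 10 s (the transient is over within 2–3 s; the margin is cheap).

## Analysis definitions

* **Cycle boundaries** are successive end-diastolic instants: local maxima
  of V at least 0.5 s apart (a refractory interval against double
  detection on noisy envelopes).  EDV/ESV are the per-cycle volume
  extrema.
* **End-systolic point**: the model does not define one, so the standard
  maximal-elastance convention is used — the sample maximizing
  P/(V − V_ref), with V_ref = 0.9 × the minimum volume of the sweep,
  refined once by replacing V_ref with the first fitted V* (skipped if
  that intercept is not below all loop volumes).  The definition is
  isolated in one function so it can be swapped.
* **ESPVR / V\***: least-squares line through the end-systolic points of a
  loading sweep (afterload m₀ for the basic variant, initial volume
  fraction of V₀ for the extended one, whose loops respond to initial
  conditions because the linear circulation retains them); V* is the
  volume-axis intercept.
* **Elastance**: E(t) = P_V/(V − V*) on the post-transient window, extrema
  over the last complete cycle.
* **Suction onset**: earliest of (a) the cycle-minimum P_V first dropping
  below the pump's own 1 mmHg resistance threshold — the most
  model-faithful observable, since it is the switching surface of R* — or
  (b) a >50 % jump of the per-beat peak-to-peak pump-flow amplitude over
  the median of the preceding five beats (the oscillation-envelope
  signature).  On the shipped ramps the pressure criterion fires first;
  the envelope criterion is the robust fallback for noisier protocols.

## Problem sizes

All shipped studies are desk-scale: control runs integrate 30 s of model
time (≈20 steady beats), loading sweeps use 3 afterloads (basic) or 6
initial volumes (extended), and the suction ramp integrates 180 s.  The
full test suite runs in about a minute; the headline-number script in
under a minute.

## Known limitations

* **The basic control loop is under-ejected.**  With the default
  parameters the shortening feedback is strong: active tension drives
  ε_c ≈ −0.01·τ_c d₀ + 0.6(V/V₀ − 1), so the Gaussian length–tension
  factor decays during ejection and caps the stroke volume near 23 mL
  (EDV ≈ 104, ESV ≈ 81 mL) — a low ejection fraction for a "control"
  heart.  A consequence is that the afterload sweep moves the end-systolic
  volume by only ≈8 mL, so the ESPVR intercept V* ≈ 31 mL is a long
  extrapolation and sensitive to the end-systolic-point convention; the
  elastance minimum (≈0.11 mmHg/mL) inherits that sensitivity.  Deeper
  ejection at the printed maximal tension σ₀ = 240 kPa is not reachable:
  the tension required at, say, V ≈ 55 mL exceeds σ₀ several-fold once the
  length–tension decay is accounted for.
* **Extended-variant pressures sag.**  The conserved total stored volume
  V + C_A m + C_S P_S + C_R P_R is fixed by the initial conditions
  (≈229 mL for the control preset), and with R_S = 0.5 mmHg·s/mL the
  steady aortic pressure settles near 50 mmHg rather than a normotensive
  80–120 mmHg.  The extended elastance extrema (E_max ≈ 2.9,
  E_min ≈ 0.16 mmHg/mL with the sweep's V* ≈ 41 mL) should be read with
  that in mind.
* Simulated trajectories are clean limit cycles: no beat-to-beat
  variability, measurement noise, respiratory coupling or baroreflex.
  Passing analysis tests on them shows the estimators are correct on ideal
  loops, not that they are robust to clinical signal quality.
* Single ventricle only; no atria, right heart, pulmonary loop or
  pump-controller dynamics.
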