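# lvloop

A multiscale simulator of left-ventricular (LV) function with an axial
rotary assist pump (LVAD), plus a pressure–volume (P–V) loop analysis
toolkit.

## Who it is for

Computational-physiology and cardiovascular-engineering users who want a
lumped-parameter heart model in which the P–V relation *emerges* from
coupled mechanical, electric and chemical dynamics — rather than being
prescribed by a time-varying elastance waveform — and who want to study how
a rotary pump interacts with a failing ventricle (loop unloading, pressure
decoupling, suction at high speed).

## The model

Nine (basic) or twelve (extended) coupled ODEs:

* **Sarcomere (microscale).** A Bestel–Clement–Sorine-type contractile
  element: strain rate v_c, strain ε_c, active tension τ_c and stiffness
  k_c, driven by a chemical activity u (s⁻¹):

      dv_c/dt = −χ v_c − ω₀² ε_c − a τ_c d₀(ε_c) + b (V/V₀ − 1)
      dε_c/dt = v_c
      dτ_c/dt = k_c v_c − (α_l|v_c| + |u|) τ_c + σ₀ u Θ(u)
      dk_c/dt = −(α_l|v_c| + |u|) k_c + k₀ u Θ(u)

  with the Gaussian length–tension curve d₀(ε_c) = exp(−β₀ ε_c²).

* **Micro→macro pressure map.** LV pressure from active plus passive wall
  stress with a cylindrical-geometry factor:
  P_V = c · γ (V₀/V)^α [d₀(ε_c) τ_c + σ_P(V)], where
  σ_P = (k₂/k₁)(e^{k₁(V/V₀−1)} − 1) and c converts the stress unit (kPa)
  to mmHg.

* **Electric activity.** A forced Van der Pol / FitzHugh–Nagumo hybrid
  (slow p, fast q) paced at 1 Hz, with mechano-electric feedback: tension
  enters through μ₁ τ_c and stretch through μ₂ V Θ(V − V₀); the chemical
  drive is u = α_u q.

* **Circulation + pump.** Ideal-diode mitral/aortic valves in series with
  resistances; either a fixed atrial pressure P_R and Windkessel relaxation
  to a constant arterial pressure m₀ (*basic*), or a dynamic systemic loop
  with aortic flow F_a through an inertance and evolving atrial/arterial
  pressures P_R, P_S (*extended*).  The axial pump in parallel with the
  aortic valve obeys L* dn/dt = P_V − m − R*(P_V) n + β ω², with a pump
  resistance R* that rises sharply once P_V drops below 1 mmHg — the lumped
  signature of inflow-cannula **suction**.

The analysis layer segments beats, computes EDV/ESV/SV, fits the
end-systolic pressure–volume relation (ESPVR) across a loading sweep to
obtain the zero-pressure volume V*, evaluates the instantaneous elastance
E(t) = P_V/(V − V*) with its extrema E_max/E_min, and detects suction
onset on pump-speed ramps.

## Worked example

Afterload sweep of the resting (control) heart, basic variant, with the
ESPVR fit:

```bash
lvloop sweep --scenario control_basic --param circulation.m0 \
       --values 50,60,70 --metrics sweep.json
```

prints to stderr:

```
[lvloop] sweep circulation.m0=50.0 hash=2e62d959e8ff7875
[lvloop] sweep circulation.m0=60.0 hash=4920d59332034f41
[lvloop] sweep circulation.m0=70.0 hash=7d7f1ab7e5231edc
[lvloop] ESPVR slope=2.083 mmHg/mL, V*=30.99 mL
```

Each run is 30 s of simulated time (≈20 steady beats after a 10 s
transient).  The slope (2.08 mmHg/mL) is the end-systolic stiffness of the
chamber: raising the arterial pressure parameter m₀ from 50 to 70 mmHg
moves the end-systolic corner up along this line, shrinking the stroke
volume.  V* = 31 mL is the volume-axis intercept of that line — the
extrapolated volume at which the activated chamber would develop zero
pressure; `sweep.json` carries the per-beat tables, the fit and the
per-condition elastance extrema (for m₀ = 70 mmHg: E_max = 2.084, E_min =
0.106 mmHg/mL).

A failing, dilated heart assisted by a slowly accelerating pump:

```bash
lvloop ramp --scenario dcm_extended --omega0 8000 --slope 33.333 --t-end 180
```

```
[lvloop] suction onset at t=107.6 s, omega=11.59 krpm (pv_threshold)
```

As the speed passes ≈11.6 krpm the cycle-minimum ventricular pressure
crosses the 1 mmHg pump-resistance threshold: the ventricle is being
over-unloaded, and the per-beat pump-flow oscillation envelope grows
sharply — the classic suction signature.  Speeds below that unload the
ventricle benignly: mean pump flow rises, aortic pressure rises, and the
LV and aortic pressure traces decouple.

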