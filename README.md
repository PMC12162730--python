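# trivalve

Design screening and optimization of **tri-tube tissue-engineered heart
valves**: a 24 mm tri-leaflet valve is assembled from three biologically
engineered collagenous tubes of diameter *D*, each cut so that a leaflet of
height *H* forms between a fixed suture line and the tube's cut edge.
`trivalve` models the tube tissue, constructs the valve geometry, simulates
its diastolic closure under back pressure, scores the closed shape with four
performance metrics, and searches the (*D*, *H*) design space for the best
compromise — the desk-scale counterpart of the commercial-FE workflow used to
design such valves, for researchers iterating on tube-based valve designs.

## Models

**Tissue.** Two hyperelastic strain-energy densities (units MPa, true
strain):

* an anisotropic model for tension-dominated loading,

  W = Σᵢ aᵢ(I₁−3)ⁱ + c₁/(2c₂)[exp(c₂(I₄−1)²)−1]
      + e₁/(2e₂)[exp(e₂(I₆−1)²)−1] + (1/d)(J−1)²,

  with fiber invariants I₄, I₆ along the tube circumferential and axial
  directions (shipped preset: a₁ = 10⁻⁴, a₂ = 0.2, a₃ = 0.34 MPa,
  c₁ = 0.44 MPa, c₂ = 7.6, e₁ = 10⁻⁶ MPa, e₂ = 3.5, d = 0.002 MPa⁻¹);

* a one-term compressible Ogden-foam model for compression-dominated loading,
  W = μ/α(λ₁^α+λ₂^α+λ₃^α−3) + μ/(αβ)(J^(−αβ)−1)
  (presets μ = 0.01 MPa with α = 14.5, β = 0.0689 and α = 27.8, β = 0.274).

Least-squares calibration to stress–strain curves uses a
model/results interface (`MaterialCalibration(...).fit().summary()`).

**Geometry.** From tube diameter D and leaflet height H: removed arc
c = πD − 24π/3 (so three retained arcs close the 24 mm ring), removed length
L = 50 − 21 − H, and nominal leaflet area LA = πDH/2. The constructed,
fully-open valve surface is meshed analytically.

**Closure.** A quasi-static membrane solver (constant-strain triangles with
the plane-stress incompressible tissue response, weak discrete-hinge bending,
frictionless penalty self-contact, dynamic relaxation with kinetic damping)
ramps the back pressure to 1000 Pa (7.5 mmHg) over 1 s and holds 0.5 s, with
both valve end rings fixed.

**Metrics** (time-averaged over ≥ 20 points in the hold window): coaptation
area CA, regurgitation area RA (short-axis projected gap), pinwheel index
PI = (l_actual − l_ideal)/l_ideal with l_ideal = 6R, and prolapse area PA
(projected leaflet overlap).

**Optimization.** A face-centered central composite design augmented to 26
maximin Latin-hypercube points samples D ∈ [15.625, 16.875], H ∈ [8.25,
13.25]; per-metric surrogates (quadratic, kriging, thin-plate RBF; selected
by leave-one-out CV) feed an elitist non-dominated-sorting genetic algorithm
(maximize CA; minimize RA, PI, PA; PI ≥ 0, PA ≥ 0) whose reported optimum
minimizes f = −ω₁CA + ω₂RA + ω₃PI + ω₄PA with equal weights.

## Worked example

```python
from trivalve import (derive_design, build_constructed_valve, simulate_closure,
                      SolverConfig, metric_samples, time_average, coaptation_length)

design = derive_design(16.0, 11.0)
print(f"leaflet area {design.leaflet_area_rounded} mm^2, "
      f"removed arc c = {design.c:.2f} mm, L = {design.L:.1f} mm")

valve = build_constructed_valve(design, n_circ=18, n_leaflet_rows=9,
                                n_below_rows=6)
result = simulate_closure(valve, config=SolverConfig(contact_detect_factor=1.0,
                                                     max_iters=600))
ev = time_average(metric_samples(result), n=20, design=design)
print(f"CA = {ev.CA:.2f} mm^2  RA = {ev.RA:.2f} mm^2  "
      f"PI = {ev.PI:.4f}  PA = {ev.PA:.3f} mm^2")
state = result.surface_at(len(result.snapshots) - 1)
cl = coaptation_length(state, gap_tol=1.2 * state.thickness)
print(f"coaptation length = {cl[(0, 1)]:.2f} mm")
```

prints (a few minutes on one core):

```
leaflet area 276 mm^2, removed arc c = 25.13 mm, L = 18.0 mm
CA = 5.87 mm^2  RA = 30.29 mm^2  PI = -0.0006  PA = 0.108 mm^2
coaptation length = 3.95 mm
```

i.e. the mid-range design coapts over a ~4 mm band (the physiological range
for a 24 mm valve), leaks through ~7 % of the lumen cross-section (mostly a
residual central gap and commissure gaps), and shows essentially no
pinwheeling or prolapse at 7.5 mmHg.

The same pipeline is scriptable from the shell:

```bash
trivalve build-valve --D 16 --H 11 --out valve.vtk
trivalve simulate-closure --D 16 --H 11 --pressure 1000 --out-dir closure_out
trivalve optimize --quick --out-dir study_out
```

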