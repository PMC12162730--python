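# Methods

This note records the models, numerical choices and their rationale, what the
synthetic inputs do and do not emulate, and the known limitations.

## Constitutive models

The anisotropic tissue energy is evaluated with its invariants exactly as
written: I₁ = tr C, I₄ = a₀·C a₀, I₆ = b₀·C b₀ (unscaled by J). An
isochoric-invariant variant (Ī = J^(−2/3) I) was considered because it makes
the rest state exactly stress-free; it was rejected because with the shipped
constants it drives the compressible/incompressible tensile-stress deviation
to ~9 % at 25 % strain — volumetric strain J−1 ≈ σd/2 grows with the
exponentially stiffening stress and the J^(−2/3) scaling then softens the
fiber response — whereas the unscaled form keeps that deviation at 0.02 %,
consistent with treating d = 0.002 MPa⁻¹ as nearly incompressible. The cost
is a negligible rest stress 2a₁ = 2×10⁻⁴ MPa at the identity (the energy is
exactly zero there). The fiber exponential is implemented as
exp(c₂(I₄−1)²) − 1 so the rest energy vanishes; the variant with −1 inside
the exponential is available via `printed_form=True` for comparison. Fiber
terms stay active for I₄ < 1 (no tension-only switch); a
`fiber_compression=False` flag deactivates them.

The foam energy W = μ/α(Σλᵢ^α − 3) + μ/(αβ)(J^(−αβ) − 1), linearized in the
true-stress/true-strain measure, has initial shear modulus G₀ = μα/2, Poisson
ratio ν = β/(1+2β) and Young's modulus E₀ = μα(1+ν); the unit tests check the
numeric unconfined-compression slope against this closed form (0.1538 MPa for
the compression-focused preset).

Deformation-mode drivers (uniaxial, equibiaxial, unconfined compression)
solve the transverse-stress-free conditions by bracketing root finding on
[0.3, 3.0] for the incompressible limit and by a warm-started vector root
find for the compressible case (the stiff volumetric term requires starting
near J = 1). Calibration minimizes summed squared true-stress residuals
(`scipy.optimize.least_squares`, bounds, per-curve weights); the identifiable
default subset is (a₂, a₃, c₁, c₂) — a₁ and e₁ are orders of magnitude below
the data's resolving power. Because c₁ trades off against the polynomial
coefficients, single noisy-fit recoveries of c₁ scatter (~±15 % at 2 %-of-peak
noise with 60-point curves); the recovery study in the tests therefore checks
the median over seeds.

## Valve construction

The two-step flatten/roll-up assembly is emulated analytically: each tube's
wall maps onto a 120° sector of the 12 mm ring; the leaflet sheet (flattened
front face, width w = πD/2) attaches to the wall along the suture curve
(default parabola through heights 21/19/21 mm; circular-arc alternative) and
the two commissure meridians. The radial inset of the leaflet grows with
normalized height s above the suture as s^0.4 and its free-edge shape is
solved so the free-edge arc length equals w: a smooth inward bow for width
deficit (D < 16 mm), an inward wrinkle ripple for width excess (D > 16 mm) —
a curve inside the ring cannot gain length without waviness, and wrinkling is
the physical signature of slack. Leaflet mesh areas above the commissure
level reproduce πDH/2 within ~3 % across the study designs.

A deterministic same-handed azimuthal bias (`twist_seed_deg`, default 8° at
the free-edge midpoint, vanishing at suture and commissures) emulates the
asymmetry of a real sutured assembly. It matters: a perfectly symmetric open
valve relaxes into a reflection-symmetric equilibrium whose central orifice
cannot close, because closing requires the free edges to slide tangentially
past each other (the pinwheel branch) — the symmetric configuration would
need unphysical hoop compression of the free-edge rim. The seed selects that
branch; designs with taut leaflets (small D, H) are insensitive to it. The
constructed state is taken stress-free (the tissue's stress relaxation
justifies resetting the reference after assembly).

## Closure solver

Thin-shell surrogate: constant-strain-triangle membranes carry the
plane-stress incompressible tissue response (thickness stretch eliminated via
λ₃² = 1/det C₂ₓ₂), with discrete-hinge bending k_b = E_b t³/12 (default
E_b = 1 MPa — the tissue's secant scale at closure strains; bending is a
regularizer, not a load path). Wall thickness is not a measured constant of
the tube batches; the default is 0.6 mm and is prominently configurable —
membrane stiffness scales linearly and bending cubically with it. An optional
tension-field mode (compressive principal membrane stresses relaxed to zero)
exists but is off by default: the limp membrane slows dynamic relaxation by
an order of magnitude, and the taut solver with the construction seed already
reproduces the qualitative closure behavior.

Statics by dynamic relaxation with kinetic damping: velocities are zeroed at
each kinetic-energy peak, masses are a per-vertex tangent-stiffness bound
(recomputed at restarts — the exponential fiber stiffening spans four decades,
so a fixed bound either destabilizes or freezes the iteration), and each of
the ≥ 30 load increments along the 1 s ramp relaxes until the nodal residual
falls below 2 % of the mean applied per-node pressure force. Contact is
frictionless vertex–triangle penalty between different leaflets, detection
distance 1.0× thickness (sheet midsurfaces in physical contact are one
thickness apart), refreshed every 5 iterations via a centroid KD-tree.
Pressure is a follower load: −p·n on leaflet faces (outflow side), +p·n on
the root above the leaflet base. Snapshots: one per ramp increment plus 21
inside the 0.5 s hold (quasi-static, so hold states are converged repeats).
The solver is deterministic; a nominal density enters only the pseudo-dynamics
and cancels from the converged statics.

Default problem sizes (the package's own choice for the study pipeline):
18 circumferential elements per tube, 9 leaflet rows, 6 wall rows below the
suture (~1 400 vertices); the resolution-stability check refines to
22 × 11 × 7 (~1.5× elements). Against that refinement, time-averaged CA and
RA move ~1 %, PI is unchanged, and PA — at ~0.1 mm², 0.02 % of the lumen —
is compared with an absolute 0.5 mm² floor because relative bands are
meaningless at that magnitude.

## Metrics

CA sums reference vertex areas of contacting vertices on the contact side
(the lower-labeled leaflet of each pair), which converges under refinement
where face-flagging overcounts; where coplanar leaflet bellies meet along a
line, an O(mesh-size) strip still registers. RA is the lumen disk minus the
union of the projected leaflets *and the projected root wall*: an undeformed
root is a vertical cylinder of zero projected area, but the root pulled
inward by leaflet tension blocks part of the lumen and must not be counted
as leak (without this the 2-D estimate overcounts ~3×). PI uses
l_ideal = 6R (straight coaptation lines, commissure–center–commissure = 2R
per leaflet); PI < 0 is flagged as free edges too short to coapt. PA counts
triple overlap once (union of pairwise intersections); a pairwise-sum
convention is available. All projections use exact polygon booleans; a
25 µm pixel-counting oracle validates RA and PA within 1 % in the tests.
Time averaging takes ≥ 20 equi-spaced points (linear interpolation) in the
hold window. Coaptation length intersects the contact band with a long-axis
plane (default azimuth: the pair's shared commissure) and reports the longest
contiguous vertical run, with a merge tolerance of twice the median edge
length.

## Design study

Face-centered CCD (9 points) on D ∈ [15.625, 16.875], H ∈ [8.25, 13.25],
augmented to 26 by the best-of-100 maximin Latin hypercube (seeded). One
surrogate per metric is selected from {full quadratic, Gaussian-process,
thin-plate RBF} by leave-one-out RMSE (the proprietary "genetic aggregation"
ensemble is approximated by this CV-selected ensemble). The genetic optimizer
is elitist non-dominated sorting with feasibility dominance (PI ≥ 0, PA ≥ 0;
negative interpolated areas are treated as constraint violations and excluded,
with reported area predictions clamped at zero), SBX crossover and polynomial
mutation; settings follow the study protocol (2000 initial samples, 400 per
iteration, ≤ 20 iterations, stop at 70 % non-dominated fraction or < 2 %
aggregate-score change). Targets (CA = 3 mm², RA = PI = PA = 0) are
aspiration levels reported with the candidates, not constraints; the selected
optimum minimizes the equal-weight aggregate among the Pareto set. Design
evaluations are cached by a configuration hash, so interrupted studies resume.

## Synthetic inputs

No tube test data are deposited, so curves are generated from the shipped
constants via the mode drivers plus seeded Gaussian noise scaled to the peak
stress — they emulate the information content of biaxial/compression tests,
not their artifacts (no grip stress shielding, no strain-rate dependence, no
speckle-tracking noise structure). Valve-state fixtures (ideal closure, fully
open, pinwheeled, prolapsed, contact bands) are analytic surfaces whose
ground-truth metrics come from the generating shapes, never from the engine
under test. Passing tests therefore demonstrate correctness of the geometry,
mechanics and measurement pipeline under idealized inputs; they do not
validate the tissue model against new experiments.

## Limitations

The membrane surrogate cannot reproduce volumetric-element stress fields
(commissure stress concentrations, through-thickness gradients), so absolute
coaptation areas and stresses are indicative; the validated observable is the
coaptation-length scale and the ordering of designs. Viscoelasticity,
strain-rate dependence, suture mechanics, systolic opening and
fluid–structure interaction are out of scope. The construction emulation
reproduces the parameterized geometry, not the assembly mechanics; its
wrinkle/bow shapes and the 8° seed are geometric idealizations whose
influence is limited to branch selection. Metric values at the default mesh
carry O(h) discretization (notably CA's line-contact strip); orderings and
bands used in the tests are stable to a 1.5× refinement.
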