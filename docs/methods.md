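# Methods

`dissectfem` models the onset of in-plane propagation of an aortic
dissection: an existing tear between the elastic lamellae of the media,
loaded by lumen pressure and axial stretch, starts to run when the bonding
ahead of its front fails.  The package combines a fibre-reinforced
hyperelastic wall, a bilinear mixed-mode cohesive interface, and a
quasi-static nonlinear finite-element solver, together with the virtual
delamination experiments used to calibrate the interface and an idealized
bilayer tube that yields the critical propagation pressure.

Units everywhere: length mm, force mN, stress kPa, energy per area
mN/mm (= N/m).  All computations are deterministic.

## Bulk material

The wall is nearly incompressible and fibre-reinforced
(Holzapfel–Gasser–Ogden form, two dispersed collagen families):

W = C10 (Ī₁ − 3) + (1/D) [ (J² − 1)/2 − ln J ]
  + Σᵢ k1/(2k2) [ exp(k2 εᵢ²) − 1 ],
εᵢ = κ (Ī₁ − 3) + (1 − 3κ)(Ī₄ᵢ − 1),

with isochoric invariants of C̄ = J^(−2/3) FᵀF and fibre directions at
±θ from the circumferential axis.  A fibre family contributes only while
εᵢ > 0; compressed fibres carry no load (a modelling convention — the
standard choice for this family of models, which prevents unphysical
compressive fibre stiffening).  The bundled layer constants come from
biaxial testing of human thoracic aorta (media: C10 = 23.0097 kPa,
k1 = 127.0692 kPa, k2 = 4.4952, κ = 0.3201, θ = 0.0008°;
adventitia: 8.2649, 71.2311, 1.6901, 0.3013, 0.001°); with θ ≈ 0 the
fibres are effectively circumferential.  D = 10⁻⁶ kPa⁻¹ makes the bulk
modulus 2·10⁶ kPa, i.e. volumetric strains are negligible.

Stress and the material tangent are analytic (decoupled
volumetric/isochoric push-forward of the invariant derivatives), verified
against finite differences of the energy in the test suite.

## Cohesive interface

Inter-lamellar bonding is a zero-thickness bilinear traction–separation
law per mode: linear rise with stiffness Kᵢ to the initiation traction
T꜀ᵢ, then linear softening to zero at S_t = 2G꜀ᵢ/T꜀ᵢ, so the enclosed
area is the critical fracture energy.  Calibrated constants of the media
(opening / circumferential sliding / axial sliding):
T꜀ = 131 / 97 / 120 kPa, G꜀ = 49 / 200 / 240 mN/mm,
K = 1638 / 35000 / 35000 mN/mm³.

Mixed-mode behaviour:

* initiation by the quadratic stress criterion
  ⟨Tn⟩²/TnC² + Ts²/TsC² + Tt²/TtC² ≥ 1 (Macaulay bracket: compression
  never initiates damage);
* a single scalar damage d evolves on the effective separation
  δ = √(⟨dn⟩² + ds² + dt²); the final effective separation is chosen from
  the current mode mix so that complete softening meets the power-law
  energy criterion Σ (Gᵢ/G꜀ᵢ)^α = 1 exactly on proportional paths
  (α = 1 by default; pure modes recover the bilinear triangles exactly);
* per-mode dissipated energies are integrated incrementally as the work
  minus the recoverable (secant) elastic energy, and the point is removed
  when the power-law criterion is met;
* unloading is secant through the origin; damage and dissipated energies
  never decrease.

Known artifact of single-damage-variable laws with very different mode
stiffnesses: under strongly opening-dominated mixed paths the sliding
traction can transiently exceed T꜀ of the sliding mode.  This affects
only free-edge regions of the shear specimens and is excluded from the
reported measurements (below).

## Finite elements

Total Lagrangian formulation; bilinear quadrilaterals (plane strain) and
trilinear hexahedra with selective reduced integration: the isochoric
energy at the full Gauss rule, the stiff volumetric term at the element
centroid.  For a decoupled strain energy this is the energy-consistent
counterpart of a constant-pressure hybrid element and keeps the nearly
incompressible response free of volumetric locking.

Interface elements are zero-thickness node pairs on coincident facets.
Separations are measured in a local frame on the deformed mid-surface
(normal from the bottom to the top side; the mode-II axis follows a
per-element reference hint, circumferential in the tube).  The element
tangent is computed by forward differences of the vectorized element
residual, which makes it consistent with frame rotation, damage growth
and the contact active set.

Penetration is resisted by a frictionless penalty: the compressive normal
stiffness blends from the cohesive stiffness Kn for intact points to
10·Kn for torn/fully damaged points, the latter with a quadratic force
onset over the penetration tolerance (10⁻⁴ mm) so the contact force is C¹
at grazing gaps.  The blend keeps the normal response continuous at zero
separation — a flat penalty with a 10× stiffness jump chatters and
prevents Newton convergence.

Follower pressure acts on the deformed surface (2-point Gauss on edges,
2×2 on bilinear facets) with its exact load stiffness.

Solution: full Newton with sparse LU, an adaptive load-factor ramp
(halving on failure, growth on easy convergence), a linear-extrapolation
predictor from the last two converged states, and a loose line search
that only rejects steps which blow the residual up (factor > 5) or leave
the physical domain (element inversion, fibre-term overflow).
Convergence: residual norm below 10⁻⁶ of the internal/external force
scale plus an absolute floor of 10⁻⁵ mN.

Softening ramps use a viscous regularization of the damage rate
(Duvaut–Lions in load-factor pseudo-time): d advances the fraction
Δγ/(μ+Δγ) toward its rate-independent target.  μ = 0 recovers the exact
law; defaults are μ = 10⁻³ for peel and tube ramps, 2·10⁻⁵ for the shear
tests, 0 for point-level evaluation and direct tension.  The energy still
to be released relative to the rate-independent target is tracked as a
stabilization diagnostic, and reported interface tractions come from the
rate-independent target state at the converged kinematics, so the
regularization lag does not bias peak values.

## Virtual calibration experiments

**T-peel** (mode I): 4.0 × 1.2 mm plane-strain medial strip, cohesive
mid-surface, 0.8 mm pre-crack; the two arms are gripped at the cracked
end and displaced ±u radially (only the opening component is prescribed —
clamping the tangential component too would create an artificial hinge;
the intact far end is held axially).  The reported plateau is the mean
force per unit width over the steady window: crack advance beyond three
cohesive element lengths and less than 80% of the bonded interface
consumed.  Default mesh 20 × 6 elements; at 32 × 8 the plateau changes by
0.5%, so the default is used throughout.  With the bundled constants the
plateau is ≈ 23.4 mN/mm, consistent with the steady-state energy balance
F ≈ G_IC/2 per arm minus a small elastic correction.
`calibrate_GIC` inverts this test by safeguarded regula falsi on G_IC
(monotone plateau), holding TnC fixed at its direct-tension value.
Below G_IC ≈ 30 mN/mm the softening branch is too steep for the coarse
mesh (element-by-element snap-through), so the calibration bracket is
[35, 80] mN/mm, which comfortably contains all physical targets.

**Direct tension** (mode I peak): rigid grips drive a uniform normal
separation across a single cohesive patch; the response is the pure
bilinear law (peak TnC, dissipation G_IC).  Driving the separation
through a compliant bulk column instead would snap back (the softening
slope exceeds the column stiffness) — the rigid-grip arrangement is the
one that actually measures the traction–separation curve.

**Interface shear** (modes II/III): plane-strain slice, 4 mm along the
sliding direction × 1 mm radial, interface at mid-thickness; front
surface fixed, rear surface displaced tangentially ("amount of shear" =
tangential displacement / 1 mm).  For the axial (rz) test the
circumferential fibres point out of plane; the per-element material frame
handles this.  The free ends peel locally (a real finite-specimen edge
effect), so the reported shear stress and dissipation are means over the
central half of the interface, which deforms uniformly (rigid-platen
kinematics, no snap-back since the bulk column is stiffer than the
sliding softening branch).

## Idealized bilayer tube

Geometry: inner radius 7.5 mm, outer 9 mm, media:adventitia = 5:3, tube
3 mm longer than the tear (1.5 mm per end).  The cohesive surface sits at
radius Ri + t·tm; elements inside the tear footprint (central angle η,
axial length s, centred) are pre-torn: no cohesive stiffness, contact
retained, and both tear faces carry the false-lumen pressure.  The
true-lumen pressure acts on the whole inner surface.  Boundary
conditions: one end axially fixed, axial stretch λ on the other, and the
circumferential displacement pinned on four cross-section planes
(θ = 0°, 90°, 180°, 270°), which removes the rigid rotation.  A
"quarter" symmetry mode (half circumference × half length) is provided
for symmetric tears and verified against the full model.

Loading is two stages: ramp λ, then ramp both lumen pressures at the
fixed ratio of the load case while watching the interface.  The critical
pressure P꜀ is the smallest true-lumen pressure at which a cohesive
element completes its damage, refined by bisection on the load factor to
1 kPa.  When the static ramp loses convergence while the interface
energy criterion is already ≥ 0.5 somewhere, the last equilibrium
pressure is reported as P꜀: under pressure control, loss of static
equilibrium at deep softening is the onset of propagation.  The critical
element's front label (axial vs circumferential, from its centroid
relative to the tear boundary) and mode mix m = 1 − G_I/G_T are reported
with it.

**Semi-analytic oracle.** The intact tube is also solved as an
incompressible axisymmetric inflation–extension problem (radial
integration of equilibrium with the same strain energy), giving
transmural Cauchy stress profiles.  The FEM intact tube at 12.8 kPa and
λ = 1.02 agrees with it to within 2% pointwise hoop stress at the
resolution used in the test suite (36 sectors over the half
circumference, 11 radial elements).

**Residual stress.** Circumferential residual stress is imposed by
classical opening-angle kinematics: the stress-free configuration is an
open sector subtending 2(π − α); closing it imposes a circumferential
prestretch k·R/ρ(R) with k = π/(π − α), and the opened inner radius is
chosen so the closed unloaded ring is self-equilibrated.  The prestrain
enters the FEM multiplicatively (per-element inverse prestrain gradient,
det = 1).  This is a deliberate simplification standing in for a
stress-mediated growth simulation: opening-angle magnitudes map to
residual-stress fields only approximately, so residual-stress results
are trend-level (inner-wall hoop stress decreases, outer increases,
critical pressure rises with α), not point targets.

## Problem sizes and what the tests show

The test-suite and acceptance-script problem sizes are the package's
default study sizes: peel 20 × 6 (calibration loop 14 × 4), shear 16 × 4,
intact-tube verification ≈ 800 hexahedra, and tear-propagation trend runs
on a deliberately coarse quarter-symmetry mesh (12 sectors × 4 axial × 3
radial).  At that coarse resolution the depth-ratio trend reproduces the
production-scale behaviour qualitatively — P꜀ decreases with tear depth,
the axial front dominates for deep tears and its damage is
opening-dominated (m < 0.5) — while absolute critical pressures sit
~10–20% below production-mesh values, and the circumferential-to-axial
direction switch across shallow depths is not resolved.  Production
studies (finer meshes, full trend grids over η, s, λ, luminal pressure
difference and opening angle) run through the `sweep`/`run-tube` CLI and
take hours, not minutes.

## Limitations

* In-plane propagation only: no radial (transmural) crack path, no
  crack-tip blunting, no fluid–structure interaction, straight tube only.
* The cohesive surface is a single predefined lamellar interface; real
  dissections can jump between lamellae.
* Mode-I properties are taken direction-independent (circumferential vs
  axial peeling differences are not modelled).
* The effective-displacement mixed-mode law can transiently overshoot a
  sliding traction cap under opening-dominated paths (see above).
* Viscous regularization delays damage slightly; with the default
  constants the delayed energy is a small fraction of the cohesive
  dissipation and is reported per run.
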