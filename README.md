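# dissectfem

Cohesive-zone finite-element modelling of in-plane aortic dissection
propagation.

Aortic dissection advances when blood, having entered the media through an
intimal tear, breaks the bonding between the concentric elastic lamellae of
the wall.  `dissectfem` is for biomechanics researchers who want to predict
*when* an existing tear starts to run: it computes the critical lumen
pressure of an idealized dissected aorta and identifies whether the damage
at the tear front is opening- or shear-driven.

The model has three parts:

* **Wall**: a fibre-reinforced, nearly incompressible hyperelastic solid
  (Holzapfel–Gasser–Ogden), one parameter set per layer,
  `W = C10(Ī₁−3) + (1/D)((J²−1)/2 − ln J) + Σᵢ k1/(2k2)(exp(k2εᵢ²)−1)`
  with `εᵢ = κ(Ī₁−3) + (1−3κ)(Ī₄ᵢ−1)`.
* **Inter-lamellar bonding**: a bilinear mixed-mode cohesive law.  Each
  mode rises linearly to its initiation traction `T_C` and softens to zero
  at `S_t = 2G_C/T_C`; damage initiates by the quadratic stress criterion
  `⟨Tn⟩²/TnC² + Ts²/TsC² + Tt²/TtC² = 1` and the point fails when the
  power-law energy criterion `Σ(G_i/G_iC)^α = 1` is met.  The mode mix
  `m = 1 − G_I/G_T` distinguishes pure opening (m = 0) from pure sliding
  (m = 1).
* **Solver**: a quasi-static total-Lagrangian FEM with zero-thickness
  interface elements, frictionless contact, follower pressure and adaptive
  Newton ramping; plus a semi-analytic thick-wall inflation solution used
  as an independent check.

Bundled constants are calibrated for human thoracic aorta: bulk layers
from biaxial testing, cohesive modes from peel / direct-tension / shear
delamination experiments (T_C = 131/97/120 kPa, G_C = 49/200/240 N/m,
K = 1638/35000/35000 mN/mm³ for modes I/II/III).

## Worked example

Drive the direct-tension virtual experiment across the medial interface
with the bundled constants:

```python
from dissectfem.constants import MEDIA, default_cohesive_params
from dissectfem.virtual_tests import run_direct_tension

curve = run_direct_tension(None, MEDIA, default_cohesive_params())
print(f"peak traction {curve.peak:.1f} kPa, "
      f"dissipated {curve.dissipated:.1f} mN/mm")
```

prints

```
peak traction 130.5 kPa, dissipated 49.0 mN/mm
```

the mode-I initiation traction (131 kPa, resolved to the load step) and
the mode-I fracture energy: the area under the computed
traction–separation curve reproduces the bilinear law it was built from.

The same interface, embedded at mid-thickness of a 4.0 × 1.2 mm
plane-strain medial strip and peeled apart, gives a steady pulling force
per unit width of ≈ 23.5 mN/mm — the T-peel energy balance
(≈ G_IC/2 per arm) minus a small elastic correction:

```python
from dissectfem.virtual_tests import SpecimenSpec, run_peel_test
peel = run_peel_test(SpecimenSpec(), MEDIA, default_cohesive_params())
print(f"peel plateau {peel.plateau:.1f} mN/mm")
```

## Command line

```sh
dissectfem run-test peel            # virtual peel, writes the curve as CSV
dissectfem calibrate-peel --target 23.0
dissectfem inflate --pressure 12.8 --stretch 1.02
dissectfem run-tube --config my_run.yaml --out results/
dissectfem sweep --vary t_ratio=0.2,0.4,0.6
```

`run-tube` builds the idealized bilayer tube (Ri = 7.5 mm, Ro = 9 mm,
media:adventitia 5:3) with a tear of central angle η, axial length s and
depth ratio t, applies axial stretch and lumen pressures, and reports the
critical pressure, the propagation direction and the mode mix at the
failing element.  Configurations are YAML with unit-suffixed keys; an
empty file reproduces the baseline study (η = 150°, t = 0.4, s = 10 mm,
λ = 1.02, equal lumen pressures, no residual stress).  Results export as
CSV tables and legacy-ASCII VTK files.

See `docs/methods.md` for the model assumptions, numerical choices and
limitations.

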