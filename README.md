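# kneefem

Subject-specific CT-based finite-element modelling of the knee joint in the
load-response (LR) phase of gait — the early-stance instant when the knee
accepts body weight and carries its largest load.

The package is aimed at musculoskeletal-biomechanics researchers who want a
fully scripted, reproducible version of the clinical CT-FEM workflow:
calibrate CT attenuation to bone density against a scanned reference
phantom, map density to stiffness element by element so the bone is
heterogeneous rather than rigid, pose the joint at gait-derived angles, load
it with the measured vertical ground reaction and computed muscle tractions,
solve the contact problem, and read off equivalent stresses and joint
contact forces. Because clinical CT data cannot be redistributed, the
package ships a synthetic-data module that generates every required input —
a CT-like phantom volume with calibration rods and known ground truth, a
parametric simplified knee mesh, and marker/force-plate/EMG gait fixtures —
so the whole pipeline runs and is tested without any download.

## The model

**Material mapping.** Voxel HU values convert to ash density by the linear
calibration ρ [g/cm³] = a·HU + b, with (a, b) fitted by least squares to
phantom rods of known density (a published 125 kV fallback,
ρ = (HU + 1.4246)·0.001·1.0580 for HU > −1 and 0 otherwise, is available
when no phantom was scanned). Density maps to Young's modulus through
Keyak's piecewise law

    E [MPa] = 0.001            ρ = 0
            = 33900 ρ^2.20     0 < ρ ≤ 0.27
            = 5307 ρ + 469     0.27 < ρ < 0.6
            = 10200 ρ^2.01     ρ ≥ 0.6

which is continuous at both breakpoints and monotone. Poisson's ratio is
0.4 for bone and all soft tissues; cartilage, meniscus and ligament solids
carry constant moduli of 20, 20 and 0.1 MPa (100 MPa for fibular
cartilage).

**Structure.** Bone parts are linear tetrahedra (target edge 1–2 mm on real
anatomy; the synthetic mesh defaults to 3 mm); a 1 mm triangular membrane
shell (E = 1000 MPa) covers the patellar patch to spread the quadriceps
pull; ligaments and tendons are two-node trusses that carry tension only,
with piecewise-linear strain–tension laws: 1000·ε N for the
cruciate/collateral ligaments and 0 / 172754·ε / 863.77 N over
ε < 0 / 0 < ε < 0.005 / ε > 0.005 for the patellar ligament and quadriceps
tendon (172754 × 0.005 = 863.77, so the ramp meets the plateau exactly).

**Posing and loading.** The femur is rigidly rotated relative to the tibia
through the LR-phase clinical angles (flexion 14.62°, varus 12.21°,
internal rotation −3.28°; intrinsic flexion → varus → internal sequence).
The proximal femur is fully fixed; the distal tibia is fixed in X and Y with
Z free, and only the vertical ground-reaction component (808.95 N) is
applied there. Flexor muscles act as nodal forces along their anatomical
lines (biceps femoris 266.26 N, semimembranosus 99.99 N,
semitendinosus + gracilis 61.11 N). The quadriceps is actuated by a 3 mm
forced displacement calibrated so the tendon truss operates on the plateau
of its law and transmits exactly 863.77 N. Articular surfaces interact
through compression-only penalty contact with Coulomb friction μ = 0.01;
the meniscus inner rim is tied to the tibial cartilage.

**Solution and outputs.** The solver is quasi-static, small-strain: sparse
assembly of tet/shell/truss stiffness, with an outer fixed-point loop over
the contact active set and the truss tension/slack set. Postprocessing
computes von Mises equivalent stress √(3 J₂) for cartilage and the
Drucker–Prager form √(3 J₂) + α·I₁ for bone (α configurable, default 0),
joint contact area, average/maximum contact pressure, the resultant joint
reaction force, and the medial/lateral compartment force split. Gait
processing subdivides stance at the Perry fractions (IC 0 %, LR 16 %,
MS 50 %, TS 83 %, PS 100 %), computes knee angles with the
joint-coordinate-system decomposition and tibia–floor angles, and builds
EMG linear envelopes (full-wave rectification, fourth-order zero-lag 6 Hz
low-pass, normalisation to the cycle maximum).

## Worked example

```sh
kneefem run-all --seed 1 --out runs/demo
```

runs synth → calibrate → map-materials → build-model → solve → post → gait
and prints one line per stage. With the default configuration the run
reports:

- `calibrate`: a = 0.000999, b = 0.00116 (true generator values 0.001 and
  0.0; the 5 HU phantom noise leaves a ~0.1 % slope error),
- `map_materials`: bone moduli spanning 2009–33469 MPa — the trabecular
  gradient and cortical shell of the phantom after Keyak mapping,
- `build_model`: quadriceps strain 0.243 from the 3 mm displacement, i.e.
  far onto the plateau, tension 863.77 N,
- `solve`: converged in 81 outer iterations with a global equilibrium
  residual of 5 × 10⁻¹² (‖Σ reactions + Σ loads‖ / ‖Σ loads‖),
- `post`: joint contact area 443 mm², average pressure 3.9 N/mm², maximum
  pressure 11.5 N/mm², contact resultant 807 N ≈ the applied vertical GRF;
  medial compartment force 965 N vs lateral 760 N — the varus pose routes
  the load medially, the qualitative hallmark of the LR phase,
- `gait`: stance events at exactly {0, 16, 50, 83, 100} % of the detected
  stance window and muscle activation/EMG-envelope correlations of
  0.98–1.00 on the synthetic trial.

`post/` also contains top-view contact-pressure and equivalent-stress maps
of the tibial surface on the default 0–5 MPa colour scale. Numbers above
are properties of the synthetic knee, not of any subject: the geometry is a
deliberately simplified parametric stand-in (see `docs/methods.md`).

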