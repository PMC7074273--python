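# Methods

This note records the model assumptions, the numerical choices, and what the
synthetic inputs do and do not emulate. It is the design rationale for the
package; empirical numbers quoted anywhere are ones the test suite or the
acceptance script computes.

## Coordinate and unit conventions

X is medial–lateral (medial = +X for the modelled right knee), Y
anterior–posterior, Z vertical (floor normal). Units are mm–N–MPa
throughout, which is self-consistent because N/mm² = MPa. Clinical angle
signs: flexion ("bending"), varus ("inversion") and internal ("inward")
rotation are positive; the LR-phase internal rotation is therefore the
signed value −3.28°.

## Material model

Bone is isotropic, linear elastic and heterogeneous: each tetrahedron gets
its own density from CT and its own modulus through Keyak's law. Two points
needed resolving:

- The mid-segment of the piecewise law is implemented as 5307·ρ + 469 MPa.
  This is the standard form of the law and the only affine segment that is
  continuous with both power segments (the jumps at ρ = 0.27 and ρ = 0.6
  are below 1 MPa, covered by a test).
- The fallback 125 kV HU→density expression is read as
  (HU + 1.4246) × 0.001 × 1.0580 with a hard zero for HU ≤ −1; phantom
  calibrations clamp ρ at zero instead.

Per-element HU sampling defaults to the mean over the four vertices plus
the centroid — cheap, deterministic, and adequate when elements are small
against the voxel size; full voxel-in-element averaging is available
(`sampling="voxels"`). A modulus floor of 0.001 MPa guards the solver
against zero-stiffness elements. Keyak's yield-stress relation is computed
on request (`with_yield=True`) and stored but plays no role in the linear
solve. Energy-dependent beam hardening and anisotropy are out of scope.

Soft tissues are homogeneous isotropic solids (cartilage 20 MPa, fibular
cartilage 100 MPa, meniscus 20 MPa, ligament solids 0.1 MPa, all ν = 0.4).
The meniscus is deliberately isotropic: a collagen-fibre-reinforced
anisotropic meniscus is a known refinement but the single-pose vertical
loading evaluated here does not require it.

## Trusses and the quadriceps actuation

Ligaments and tendons resist only stretch, so they are two-node truss
elements with tension-only piecewise-linear strain–tension laws (zero below
ε = 0, linear interpolation between breakpoints, terminal slope beyond the
last one — zero slope reproduces the tendon plateau, a nonzero terminal
slope the unbounded 1000·ε ligament ramp). The solver linearises each truss
on its current law segment (secant stiffness k_seg/L₀ along the axis plus a
constant-force correction), so a converged solution carries the exact
nonlinear tension.

The quadriceps is not applied as a force: a prescribed 3 mm displacement at
the actuation anchor stretches the tendon truss beyond its 0.005 plateau
knee, and the plateau value (863.77 N) is exactly the traction the muscle
must transmit. `calibrate_forced_displacement` verifies the plateau is
reached (strain = 3/L₀ mm with the synthetic anchor ~12 mm away, i.e.
strain ≈ 0.24) and warns with the achieved ramp tension when it is not.
Ligament pre-strain is not modelled.

## Pose

The femur (with its shell patch, anchor and truss endpoints) is rigidly
rotated about the centroid of its inferior surface using the intrinsic
flexion → varus → internal sequence; the joint-coordinate-system
decomposition used for gait angles is the exact inverse, which the
round-trip tests exploit. The source convention leaves the rotation order
unspecified; this sequence matches the usual clinical JCS ordering. After
rotation the femur is translated vertically so its lowest inferior node
clears the highest opposing surface node by `reseat_clearance` (default
0.1 mm): posing is a rigid placement, and contact closure is the solver's
job. The tibia stays vertical in the FE model; the measured tibia–floor
angles are carried for reference and validated in the gait module.

## Contact

Node-to-surface penalty contact: each slave node is projected onto the
master facets (KD-tree candidate search, exact closest-point on triangle),
penetration is penalised along the master outward normal, and friction is a
penalty-regularised Coulomb stick-slip law implemented with a secant
tangential spring — full stiffness while |F_t| < μ|F_n|, reduced to
μ|F_n|/|t_rel| once the cap is reached, so slipping nodes transmit exactly
the capped force yet stay implicit. μ = 0.01 by default (nearly
frictionless; the regularisation error is negligible). Tied pairs (the
meniscus inner rim on the tibial cartilage) are bonded in all three axes at
their reference projection. The default penalty stiffness per slave node is
100 × (softer neighbouring part's median modulus) × (tributary area) per mm,
configurable per pair.

Resolution of the two nonlinearities (contact active set, truss active set)
is an outer fixed-point loop around a sparse linear solve with three
robustness devices, each covered by tests:

- **Step limiting.** Parts supported only through contact would overshoot
  the gap closure by orders of magnitude on early iterations and bounce on
  the penalty springs; displacement increments are capped (default 0.5 mm)
  so gaps close progressively. Convergence is only declared on an uncapped
  step.
- **Frozen pairing.** Once the active sets repeat, the facet pairing and
  normals are latched and only gaps are re-evaluated; re-pairing between
  near-equidistant facets (a slave node over a shared master vertex)
  otherwise sustains micro-oscillations at the 10⁻⁵ mm level forever.
- **Stabilisation.** Weak grounding springs (10⁻⁴ N/mm) support floating
  parts during the iterations; a final stabilisation-free solve with the
  converged active sets restores exact global equilibrium, which is why
  converged runs report ‖Σ reactions + Σ loads‖/‖Σ loads‖ at round-off
  level (the acceptance bound is 10⁻⁶).

Convergence requires stable active sets and a maximum displacement
increment below 10⁻⁸ mm within 100 iterations (200 for the full knee run);
non-convergence raises with the last increment. Kinematics are small-strain
and small-displacement throughout, consistent with a static linear
analysis; the synthetic knee run reaches ~8 mm of rigid gap closure, which
stretches that assumption but leaves the contact-equilibrium bookkeeping
exact.

## Elements

tet4: standard constant-strain tetrahedron; its stiffness is symmetric PSD
with exactly six rigid-body modes, and the assembly reproduces any linear
displacement field exactly (patch test, also run on the generated knee
mesh). Shells are membrane-only constant-strain triangles (in-plane
plane-stress stiffness × thickness, no bending): their role here is to
spread the quadriceps pull over the patellar patch, which membranes
accomplish; out-of-plane stiffness is absent, so shell-only fixtures must
constrain the normal direction. Stress recovery is per element (solids:
full tensor; shells: membrane tensor re-embedded in global axes).

## Postprocessing

Equivalent stress: von Mises √(3 J₂) for cartilage/meniscus, Drucker–Prager
√(3 J₂) + α·I₁ (clamped at zero) for bone. The pressure-sensitivity α is a
free parameter defaulting to 0 — at which the two criteria coincide —
because no cohesion/friction-angle constants accompany the criterion in the
source convention; tests cover the reduction and the α > 0 behaviour.
Contact summaries are nodal: a slave node contributes its tributary area
when its normal traction exceeds 10⁻⁹ MPa, the average pressure is
area-weighted (Σ|F_n|/Σa), and the resultant is the vector sum of nodal
contact forces. The medial/lateral split classifies slave nodes by the side
of a configurable partition plane (default X-normal through the joint
centre). Stress maps default to the 0–5 MPa colour range.

## Gait processing

Stance is the longest interval with vertical GRF above a 20 N threshold (no
threshold is fixed by convention; 20 N is the common force-plate choice and
is configurable), subdivided at the Perry fractions exactly. Segment frames
are built from the lateral Plug-In-Gait subset — femur: knee marker, hip
point (midpoint of the right ASIS/PSIS markers, a documented simplification
of the proprietary hip-centre regression), lateral thigh marker; tibia:
ankle, knee, lateral shank markers — and knee angles are the intrinsic
flexion → varus → internal decomposition of the relative rotation, which is
invariant under global rigid motion. The EMG envelope rectifies, filters
with a second-order Butterworth run forward and backward (the standard
reading of "fourth-order zero-lag") at 6 Hz, clips filter undershoot at
zero, and normalises by the envelope maximum over the cycle (envelope
rather than raw maximum, so the output maximum is exactly 1 and
re-normalisation is idempotent). Activation similarity is the zero-lag
Pearson correlation on a common percent-cycle axis.

## What the synthetic data emulates — and what it does not

The phantom volume provides exactly the features the material pipeline
consumes: soft-tissue background at 40 HU, an air border at −1000 HU, two
box-shaped bone bodies with a 3 mm cortical shell at 1.8 g/cm³ and a
trabecular density gradient (0.25–0.55 g/cm³ along the shaft), and
calibration rods of known density whose HU values invert the true linear
calibration exactly, so the zero-noise round trip is exact by construction
and noisy recovery is testable against the fitted standard errors.

The knee mesh is parametric and intentionally non-anatomical: femur and
tibia blocks (the femur's inferior surface crowned by two shallow
paraboloid condyles, radius 80 mm, so varus contact localises to a patch
rather than a knife edge), a conforming 2 mm tibial-cartilage layer, two
10 mm meniscus spacer blocks tied at their inner rim, a patellar shell
patch on the femur anterior face, and six labelled trusses. Default
condition values are the study conditions: LR angles, 808.95 N vertical
GRF, the fixed muscle tractions, μ = 0.01, 3 mm actuation. The gait
fixture holds the LR pose statically while translating rigidly (so angle
recovery is exact up to marker noise), shapes the vertical GRF as a
double-hump curve with a steep heel-strike onset normalised to the
prescribed peak, and synthesises EMG as amplitude-modulated bursts.

Passing tests on these fixtures therefore demonstrate that the *machinery*
is correct — calibration recovery, material mapping, equilibrium, contact
bookkeeping, tension-only behaviour, angle and envelope processing, medial
load dominance under varus — not that any subject-specific stress value is
reproduced. Subject-level outputs (contact area, pressures, joint reaction
force) depend on the real anatomy, which no synthetic stand-in supplies;
they are reported for the synthetic knee as qualitative, property-checked
quantities only. Likewise out of scope: image segmentation, inverse
dynamics (muscle tractions are consumed as given constants), horizontal
GRF components in the solve (carried in the data model, excluded by
default), and dynamic or multi-phase loading.

## Problem sizes and defaults

The default synthetic knee uses a 3 mm target edge (≈12 000 tets, ≈8 500
DOFs), which the full pipeline solves in ~80 outer iterations; tests and
the pipeline's own determinism check run at 4 mm. The phantom volume is
36 × 36 × 52 voxels at 1.5 mm. These sizes were chosen so the whole suite
exercises every code path at desk scale; all of them are configuration
parameters, and finer meshes change only runtime, not code paths.
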