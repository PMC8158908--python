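# Methods

## Coordinate frame and poses

All computations use one fixed, right-handed pelvic frame for a right hip:
+X lateral→medial, +Y posterior→anterior, +Z inferior→superior, origin at
the hip center of rotation (COR).  The pelvis is fully constrained.  The
COR is taken as the center of a least-squares sphere fitted to the
articular surface of the femoral head (algebraic linear fit; exact on
noise-free data, sub-0.05 mm error at 0.1 mm isotropic noise).

Pose operations are rigid rotations about axes through the COR:

* **Femoral version** — rotation about +Z; positive increases anteversion.
  Sweep versions are absolute targets; the builder bakes in the native
  20° anteversion and the sweep applies the difference.
* **Hip flexion** — rotation about +X with the sign that moves the distal
  shaft anteriorly.  The flexion axis is the pelvic medial–lateral axis
  regardless of femoral version (pure sagittal-plane flexion).
* **Cup pose** — the cup pole (apex direction) is the radiographic
  inclination/version axis: with inclination *i* and version *v* the
  opening axis is (−sin i cos v, sin v, −cos i cos v), the apex its
  negative.  Anatomic and operative angle conventions are supported via
  the standard interconversions; which convention the original study used
  is not stated, and onsets shift several degrees between them.

## Synthetic anatomy

No imaging data is used anywhere; the geometry is rebuilt from printed
dimensions as deterministic surfaces of revolution (bit-identical on
rebuild at fixed resolution, default target edge length 1 mm).

**Femur** (about the versioned neck axis): articular spherical cap of
radius 27 mm; chamfer cone; 42 mm neck cylinder to the neck–shaft junction
at 35 mm; 30 mm × 120 mm shaft stub along the inferior axis.  Neck length,
shaft size and skirt width are not printed in the source study; values
were chosen once so that the neck remains the proximate impingement
structure.  The articular cap ends where the head sphere meets the
cylindrical ream of the femoral component.  With a 3 mm component wall the
ream diameter is 48 mm and the cap extends to a polar angle of
180° − arcsin(24/27) ≈ 117.3°.  This cap extent matters: it is the only
way femoral version can influence the contact mechanics of an otherwise
spherically symmetric bearing (below).

**Cup**: spherical cap of radius 27.08 mm (27 mm + 80 µm radial
clearance) about its pole, plus a 5 mm annular "skirt" in the rim plane
standing in for the peri-acetabular bone margin.  The clearance is
interpreted as radial (cup inner radius − head radius); the 80 µm value
also serves as the contact-initiation distance of the bearing model.
The coverage arc defaults to 156°.  The shell is sub-hemispheric by
design; in this parametric model the arc is additionally bounded above by
the requirement that every studied configuration (version ±30°, cup
40–50° × 15–25°) be impingement-free in neutral stance, which caps it at
157.7° — a hemispherical cup would place the anteverted femora in grazing
rim contact before any flexion.  156° leaves a 2° margin for mesh
faceting.  Onset angles move by roughly 0.8° per degree of coverage arc,
so this single unprinted parameter dominates absolute onsets.

Material constants (cortical 20 GPa/0.3, cancellous 1 GPa/0.3, CoCr
200 GPa/0.3, PMMA cement 2 GPa/0.19) are carried for the physical
foundation mode; cortical shell and cement mantle are not explicit mesh
layers — their compliance is absorbed into the foundation stiffness.

## Impingement analysis

At each swept flexion angle (default 1° steps, 0–90°) the femoral
neck/shaft faces are tested for contact against the posed cup + skirt
mesh.  Contact detection is an exact triangle–triangle proximity query
(minimum over edge–edge and vertex–face candidate distances, plus an
edge-piercing test for intersecting pairs), pruned by a KD-tree broad
phase over face centroids with per-face circumradii; the brute-force
all-pairs route through the same narrow phase is retained as the pruning
oracle.  Onset is the first angle with any contacting pair at zero
tolerance (true touch/interpenetration); detection already at 0° warns,
since the reference models start impingement-free.  Impingement area is
the summed area of neck faces whose centroids lie inside the obstacle
solid (cup wall sector + skirt slab), reported with an anatomical octant
label of the patch's circumferential position on the neck.

For an axisymmetric neck and a circular rim, onset reduces to a closed
form: contact begins when the angle between the neck axis and the cup
pole falls below (rim polar angle + arcsin(r_neck/R_rim)).  This both
validates the mesh pipeline (onsets agree within a degree) and exposes a
structural limitation: along the flexion trajectory of the anteverted
femora that angle moves *away* from the rim for every admissible coverage
arc, so anteverted configurations cannot impinge by 90° in this model.
Reproducing simultaneously the reported anteverted (70°) and retroverted
(30°) onsets would require two incompatible rim thresholds; the
anteverted-side onset in the original cadaveric geometry evidently
involves anatomy (native acetabular margin, extra-articular structures)
that an axisymmetric parametric model does not contain.  The retroverted
onsets land at 54–76° here (vs 30–?° reported), monotone in version and
delayed by steeper/more anteverted cups, matching every reported trend
but overestimating the absolute angles.

## Bearing contact (elastic foundation / discrete element)

The cup's inner surface is discretized into n equal-area elements
(Fibonacci spiral over the coverage cap; default n = 20 000, peak
pressures stable to <2 % on doubling n).  Head and cup are rigid
conforming spheres; springs act at the interface.  For head-center
displacement u, element pressure is k·(u·e − c)⁺, and Newton iteration
with backtracking solves Σ p A e = F to a relative residual of 1e−10
(asserted ≤ 1e−6 everywhere).  Friction is omitted: in a near-concentric
conformal bearing, tangential traction perturbs the normal pressure at
second order; the printed coefficient (0.15) is recorded in the implant
spec for documentation.

An element can bear load only if it is also covered by the head's
articular cap (117.3° half-angle about the posed cap pole).  At the 0°
and 45° load cases the contact patch (half-angle ≈ 30°) sits deep inside
both caps for every version, so pressures are version-insensitive there —
as reported.  At the 90°-flexion (sitting) load with a retroverted femur
the cap pole rotates away until the patch is truncated at the cap edge
(edge margin 15.7° for 30° retroversion vs ≈ 27° patch half-angle):
contact area falls, peak pressure rises, and the patch centroid shifts to
the anterior bone–implant interface in the femur frame.  This reproduces
the reported phenomenology exactly; the magnitude of the increase
(+8.7 % here vs 18 % reported) is smaller, as expected from a rigid
foundation with no edge stress concentration — a finite-element rim
contact amplifies the edge pressure in a way independent springs cannot.

**Polar-load closed form.**  For a load along the cup pole the
axisymmetric equilibrium has an exact antiderivative,
F(u) = 2πR²k[u(1−x₁³)/3 − c(1−x₁²)/2] with x₁ = max(c/u, cos θ_max),
solved by bracketed root finding; peak = k(u−c), contact half-angle
arccos(c/u).  The 3-D solver matches it to 0.02 % and is asserted within
1 %.

**Foundation stiffness.**  Two modes: *physical*, k = E/t with the
cancellous modulus over a configurable 5 mm support layer (200 MPa/mm);
and *calibrated* (default), k bisected so that a documented reference
case reproduces a target peak.  The study's single printed pressure
anchor is the retroverted sitting-load peak 6.3 MPa described as an 18 %
increase over its neutral comparator, which fixes the comparator at
6.3/1.18 = 5.34 MPa; the default calibration therefore targets 5.34 MPa
on the neutral-version / sitting-load / cup 50°/15° case, giving
k = 540 MPa/mm — between the cancellous-only estimate and stiffer
layered-support values, i.e. physically plausible.  The calibration case
and target are ordinary configuration entries, not constants in code.

**Loads.**  The three tabulated in-vivo peak forces are applied at the
COR with components taken as magnitudes along +X/+Y/+Z so the resultant
seats the head superomedially; vectors are not re-rotated with flexion
(each row already corresponds to its activity posture).  Magnitudes are
validated against the printed %BW values (238/251/156 at 836 N reference).

## Sweep and comparisons

The experiment enumerates versions × cup poses × loads (60 records,
version outer / cup middle / load inner), running impingement and contact
independently per configuration (contact at the nominal activity posture
even if impingement would truncate motion).  Derived tables: percent peak
pressure change per version against the neutral-version row at the same
cup pose and load (the comparator the original study leaves implicit),
and percent contact-area change for inclination 50° vs 40° at fixed
version/cup-version/load.  Reruns with fixed options are bit-identical;
there is no randomness anywhere in the pipeline (test RNGs are seeded).

## Problem sizes and runtime

Default study conditions: 1 mm meshes (≈54 k femur faces, ≈14 k cup
faces), 1° flexion steps, 20 000 bearing elements.  The full 60-config
sweep runs in ≈80 s on one CPU; the acceptance recomputation in ≈10 s.

## What the synthetic model does and does not show

The generator emulates a single cadaveric geometry from printed
dimensions.  It preserves: bearing dimensions and clearance, neck size and
orientation angles, cup poses, load vectors and the articulation topology.
It does not contain: non-circular native acetabular rim and periarticular
bone, aspherical head/neck junction anatomy, cortical/cement layering, or
deformable continua.  Passing tests therefore demonstrate the geometric
and contact *mechanisms* and trend reproduction, calibrated to the
reported pressure scale — not patient-specific accuracy of absolute onset
angles or FE-grade stress fields.  Known quantitative gaps, all traceable
to the simplifications above: anteverted-side impingement onsets (absent
≤90°), retroverted onsets ≈20° late, and a +8.7 % (vs 18 %) retroversion
pressure increase.
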