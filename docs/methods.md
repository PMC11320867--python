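# Methods

This note documents the models, conventions and defaults behind the
package, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
demonstrate about clinical data.

## Data model and geometry conventions

All masks and HU volumes live on an `ImageGrid`: an axis-aligned,
anisotropic voxel lattice described by spacing (mm), the world coordinate
of the **center** of voxel (0, 0, 0), shape and a frame-of-reference
label. Voxel indices are 0-based; array axes are (x, y, z) with z the
axial direction. Two grids are *compatible* (boolean mask algebra is
allowed) only when spacing, origin, shape and frame all agree.

The package performs **no registration**. Images of one patient are
assumed co-registered upstream (rigid, bone-based); grids in one frame
with different spacing are unified by nearest-neighbour resampling at the
target voxel centers. Nearest neighbour is deliberate: masks must remain
strictly binary, the operation is deterministic, and for structures much
larger than a voxel it is volume-stable. Cross-grid metric comparisons
resample the *test* structure onto the *reference* grid; the tool used in
the original clinical analysis does not document its convention, so
fixing the reference grid is our reproducibility choice.

## Congruence metrics

* **DSC** = 2·|A∧B| / (|A|+|B|).
* **Surface set**: mask voxels with at least one 6-neighbour outside the
  mask (array-border voxels count as surface); distances are Euclidean
  between surface-voxel centers, in mm, spacing-aware.
* **HD**: maximum of the two directed maximum nearest-neighbour surface
  distances. The true maximum is used, not a percentile, because the
  artefact-thickness analysis interprets HD as the *largest* protrusion
  expected.
* **AHD**: maximum of the two directed mean nearest-neighbour surface
  distances (the common "average Hausdorff" form); the arithmetic-mean
  combination is available via `combine="mean"`.
* **Congruence bands**: high iff DSC > 0.7 and AHD ≤ 1 mm; low iff
  DSC < 0.7 and AHD > 1 mm; otherwise indeterminate. The 0.7 threshold
  accommodates small structures, which DSC penalises.
* Metrics involving an empty mask raise instead of returning infinities,
  so cohort summaries can never silently absorb degenerate cases.

Surface-distance routines are validated against an all-pairs brute-force
oracle on random anisotropic grids (agreement to 1e-9 mm).

## Margins and target pathways

Isotropic expansion includes a voxel iff its center lies within the
margin (Euclidean mm) of some source-voxel center, computed with an exact
Euclidean distance transform restricted to the padded bounding box. A
1e-9 mm slack guards against floating-point noise only; a 3 mm expansion
of a single voxel on a 1 mm grid yields exactly the 123 lattice points
with x²+y²+z² ≤ 9.

Two CTV pathways are built from a raw (anatomical) CTV:

* **adjusted**: brain ∪ (brain ⊕ a ∧ B_sCT ∧ (CTV ⊕ a)) with
  a = 3.5 mm by default, then CTV_a = CTV ∧ adjusted brain and
  PTV_a = CTV_a ⊕ 3 mm. The clinical procedure is a *manual* extension of
  the brain "by approximately 3.5 mm beyond the bone" near the target;
  the constructive form above (grow brain, restrict to sCT bone and to
  the target neighbourhood) is this package's formalisation of it. The
  restriction to the target neighbourhood reflects the reading that the
  extension was applied only where the artefact could affect the target.
* **non-adjusted**: CTV_na = CTV ¬ B_sCT, PTV_na = CTV_na ⊕ 3 mm.

The default adjustment of 3.5 mm can instead be derived at run time from
thickness estimates via `margin_recommendation` (mean thickness rounded
*up* to the nearest 0.5 mm — a margin should never round down).

## Coverage pipeline

For fraction i, with PTV_a as the control region in **both** pathways:
IV_CBCT = B_CBCT ∧ PTV_a, IV_sCT = B_sCT ∧ PTV_a, V_A = IV_sCT ¬ IV_CBCT,
V_uncov = V_A ¬ PTV_eval. Reusing the PTV_a-based V_A for the
non-adjusted evaluation keeps both pathways scoring the same artefact
volume. Note the uncovered volume is the artefact volume minus the
evaluated PTV — V_A is contained in PTV_a by construction, so the
adjusted pathway yields exactly zero on a shared grid, and any nonzero
adjusted value in practice indicates cross-grid or registration effects.
`uncovered_fraction_pct` is 100·V_uncov/V_A, defined as 0 when V_A = 0.

## Artefact detection, classification and gap QA

Candidate SFD artefacts are 26-connected components of B_sCT ¬ B_ref
above a volume floor (0.01 cc, configurable) that suppresses resampling
speckle. Classification is by the component's side contacts:

* **1c** — no face adjacency to the reference bone (detached island);
* **1a** — touches the brain on the inside *and* non-brain tissue/air on
  the outside (through-going);
* **1b** — attached to bone with brain-side contact only.

The original classification is visual; this adjacency rule is our
operationalisation. An earlier variant using one-voxel bone surface
bands was rejected because a through-going artefact's outward cap shields
the adjacent outer bone band, making 1a undetectable.

Bone gaps are components of B_ref ¬ B_sCT. Gap length is the maximal
chord between voxel centers (convex-hull accelerated); a gap is *total*
when it contacts both the brain side and the exterior side of the skull
(the interior is inferred from the cavity structure of the reference
bone's complement when no brain mask is supplied), else *partial*. Gaps
longer than 30 mm are flagged `review`, per the adopted 3 cm tolerance.

## Auto-contouring emulation

The three treatment-planning-system behaviours are emulated, not
replicated (the vendor's filters are proprietary): *search body* is a
global HU threshold (−350 HU on CT, −850 HU on sCT) with
largest-component selection, hole filling and one binary opening;
*flood fill* is seeded region growing within a ±goodness HU window
(default connectivity 6); the *segmentation wizard* windows around an
organ reference HU (brain 40, bone 1000, goodness ±300 HU), clears axial
planes farther than 10 mm from the main component's plane range, and
dilates by 0.5 mm. Defaults are calibrated on the phantom only.

## The synthetic phantom

The phantom emulates the statistical structure the analysis assumes, not
anatomy: an ellipsoidal head (default half-axes 65/80/60 mm) of soft
tissue (40 HU) in air (−1000 HU); a 6 mm scalp; a closed 6 mm
ellipsoidal-shell skull (1000 HU); brain filling the interior; a 20 mm
spherical CTV abutting (or, configurably, overlapping) the inner skull.
Grids default to the clinical acquisition: CT 1.00/1.00/2.00 mm, sCT
0.68/0.68/1.00 mm, CBCT 1 mm isotropic, all in one frame.

Artefacts are capped cylinders normal to the local skull surface. A 1a
site includes a small burr hole in the *true* bone (the device's kerf)
which the sCT renders as bone together with a 1.5 mm outward cap and an
inward protrusion of the requested thickness; 1b adds the inward
protrusion only; 1c is a detached bone-valued sphere 3 mm below the
inner surface. Paired device delineations (mid-skull to inner surface on
CT; extended by the protrusion on sCT) are emitted for thickness
analysis. Bone gaps are rectangular skull patches (6 mm tangential
width) whose slab extents are chosen so the patch's maximal chord equals
the requested length; partial gaps remove the outer half-shell only.
CBCT volumes are the true bone geometry rigidly shifted per fraction
(default sub-millimetre set-up error). Gaussian HU noise (σ = 20 HU) is
added per modality and never alters truth masks. Identical spec and seed
give bit-identical volumes.

Cohorts draw per-phantom artefact thickness uniformly from 2.0–4.5 mm,
mirroring the clinically observed 5–95 % band, with 5 CBCT fractions per
phantom by default.

**What the phantom does not emulate**: partial-volume effects (HU are
assigned by voxel-center membership, so auto-contours recover truth
almost exactly — the congruence numbers on phantoms are upper bounds, not
forecasts for clinical images), CBCT streak artefacts, MR noise
structure, real anatomy (sinuses, foramina, ventricles, dental work) and
non-rigid misalignment. Passing parameter-recovery tests demonstrates
correctness of the operators under the stated geometry model, not
clinical segmentation accuracy.

## Numerical behaviour and known limitations

* Thickness estimates carry a small negative bias (≈0.3 mm at the
  default grids) because surface-voxel centers sit inside the continuous
  protrusion tip; recovery error stays below one sCT voxel diagonal
  (1.39 mm) in mean absolute terms.
* Cross-grid DSC of thin shells is limited by nearest-neighbour
  staircase effects (≈0.93 for the skull between the 2 mm CT slices and
  the 1 mm sCT grid) even for identical geometry.
* Gap lengths measure ≈0.5–1 mm short of the nominal chord (voxel-center
  shortfall at the patch rim); QA decisions at exactly the 30 mm
  tolerance are therefore measurement-limited, as they would be
  clinically.
* The margin-policy experiment (uncovered volume versus PTV margin) uses
  an inner-surface (1b) artefact family with the CTV overlapping the
  inner skull and a shift-free, sCT-grid CBCT: in that controlled
  geometry the non-adjusted uncovered volume is non-increasing in the
  margin and vanishes once the margin reaches the artefact thickness.
  With a through-going (1a) artefact the burr-hole fill deep inside the
  shell belongs to V_A but lies farther from CTV_na than any practical
  margin, so the uncovered volume plateaus above zero instead.
* Validation problem sizes: unit tests run on a reduced head (34/38/30 mm
  half-axes); acceptance checks and `scripts/acceptance.py` use the
  default geometry with cohorts of 6–30 phantoms and up to 5 fractions,
  sizes at which every reported quantity is stable to well within its
  asserted tolerance.
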