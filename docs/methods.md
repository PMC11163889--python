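# Methods

`discmorph` measures the morphology of pediatric intervertebral disks
(IVDs) from labeled segmentation volumes — annulus fibrosus (AF) and
nucleus pulposus (NP) masks, one pair per spinal level from T1–T2 down to
L5–S1 — and summarises how that morphology changes across a growing
cohort. Because no public pediatric disk-segmentation dataset exists, the
package also ships a phantom generator whose growth parameters are
calibrated to published reference trajectories, so the whole chain can be
validated against known ground truth.

## Per-disk measurement model

All geometry is computed in "grid-millimetre" space: voxel `(i, j, k)`
sits at `(i, j, k) * spacing`, a voxel-centre convention with 0-based
indices. NIfTI label maps must have axis-aligned (permutation/flip)
affines; the affine supplies the anatomical meaning of each grid axis.

**Frames.** Each disk gets a right-handed orthonormal frame (x
left–right, y anterior–posterior, z cranial–caudal) from the inertia
axes of its AF: eigenvectors of the central second-moment (covariance)
tensor of AF voxel centres. The covariance tensor shares eigenvectors
with the physics inertia tensor; ordering by descending spatial extent
makes the convention deterministic — the smallest-extent axis is the
candidate z. Candidate axes are signed toward scanner cranial/anterior;
x is recomputed as y × z. Near-equal moments (relative gap < 5%) raise a
degeneracy flag; frames for disks tilted ~90° from anatomical raise an
error rather than guessing.

**Rotation correction.** Patient rotation in the scanner is removed by a
patient-specific sagittal plane through three AF centroids: the most
cranial level, the first lumbar level, and the most posterior AF of the
whole spine (if the most posterior one coincides with either anchor, the
next most posterior is used, since three distinct points are needed).
Each disk frame is then rotated about its own z by the unique angle in
(−90°, 90°] that brings y into that plane, choosing the in-plane solution
that keeps y anterior.

**Measures.** With the corrected frame:

- *Height H* (mm): chord length of the IVD (AF ∪ NP) along z through the
  IVD centroid. The line is supersampled at min(spacing)/4 and membership
  is evaluated by trilinear interpolation of the binary mask with the
  digitized surface at the 0.5 level; the two 0.5-crossings are refined
  by linear interpolation between samples. The interpolated crossing
  averages out the voxel staircase of tilted surfaces — a nearest-voxel
  test is quantized to whole voxel layers and loses up to half a slice on
  tilted disks. Internal gaps wider than the gap-closing radius remain
  part of the chord. A mean-height variant (chord averaged over the
  footprint on a 1 mm grid) is exposed via `method="mean"` for
  sensitivity checks; the default is the single centroid chord.
- *Cross-sectional area A* (mm²): the transverse plane through the IVD
  centroid normal to z, resampled on a 0.2 mm grid (bounding box + 2 mm
  margin) with nearest-voxel membership; area = hits × cell area.
- *Slenderness S = H/√A*: unitless; scale-invariant by construction.
- *Volumes*: voxel count × voxel volume for AF and NP; V_IVD = V_AF +
  V_NP holds exactly by construction.
- *Nucleus offset*: NP centroid minus whole-IVD centroid projected on
  the frame axes (+x left, +y anterior, +z cranial), signed.

Supersampling steps (line min-spacing/4, plane 0.2 mm) keep the
discretization error of the measures well below the ~0.5 mm in-plane /
3–4 mm slice-thickness uncertainty that sagittal MRI segmentations carry
anyway.

**Gap closing.** Segmentation masks are first closed with a metric ball
of diameter 1 mm (configurable), emulating the gap-filling of surface
"wrap" post-processing. The closing is built from exact Euclidean
distance transforms with per-axis sampling, so the radius is respected in
millimetres under anisotropic voxels; the output always contains the
input, and a slit along a coarse axis wider than the radius correctly
survives. Surface smoothing, the wrap tool's other effect, is deliberately
not modelled: every downstream measure is integral- or centroid-based and
insensitive to voxel-scale surface texture.

## Phantom generator

Each disk is an elliptic cylinder with a superelliptic footprint
(exponent 2.5, semi-axis aspect b/a = 0.7 — a slightly squared-off disk
outline; the reference data constrain only the area, not the outline
shape) containing an ellipsoidal nucleus (in-plane aspect 0.7, z
semi-axis 0.35 × disk height). Given target height, area, NP:IVD volume
ratio and AP nucleus offset from the growth table, the AF semi-axes are
derived from the area and the NP is sized so the volume ratio is exact
before voxelization. Disk-to-disk biological variation is multiplicative
log-normal jitter, mean-corrected so `jitter_sd` is the coefficient of
variation while all sizes remain positive; a jittered nucleus that would
pierce the annulus envelope is shrunk back inside with a logged warning.

Spines stack 17 disks (mirroring 126 × 17 = 2142 disks in the reference
cohort's counting; level indices 1–17 map to the T1–T4 / T5–T8 / T9–T12 /
L1–L5 groups by index ranges) along a fixed two-arc sagittal profile
(30° thoracic kyphosis, 40° lumbar lordosis, all ages — the curvature
exists to exercise the frame correction, not to model sagittal-profile
development), separated by vertebral-body gaps of 1.2 × disk height +
6 mm. A whole-spine rigid pose (Euler angles) emulates patient
positioning. Default spacing is 3.5 × 0.5 × 0.5 mm with the coarse slice
axis left–right, as in sagittal MRI; validation suites use 0.5 mm
isotropic grids. Voxels are labeled by the schema AF(k) = 2k − 1,
NP(k) = 2k. Rasterizing a single disk places its centre at an
incommensurate sub-voxel offset: exact coincidence of analytic surfaces
with voxel-centre planes is a measure-zero configuration in real data
but systematic on centred grids, and it inflates surface-voxel counts.

### Calibrated growth table

The default table stores piecewise-linear anchors over age 0–18 per
(level group, sex):

- **Height**: low-thoracic 4 → 7 mm and lumbar ~5 → 10 mm over the first
  decade, flat afterwards; upper/mid-thoracic plateau between 4.2 and
  5.4 mm by age 8. Both sexes share the 10 mm lumbar adult anchor.
- **CSA**: birth-to-18 growth factors ×4.2 (M) / ×2.5 (F) upper-thoracic
  and ×5.2 / ×3.9 lumbar, with 45% of the total gain realised by age 4
  (growth is steepest in infancy). Mid/low-thoracic factors are not
  published and are interpolated (M ×4.4 / ×4.8; F ×3.0 / ×3.4).
- **NP:IVD ratio**: 10–12% at all ages in the upper/mid-thoracic spine;
  rising to 19%/20% (M/F) low-thoracic and 23%/25% lumbar by age 18.
- **AP nucleus offset**: zero in infancy everywhere, drifting by age 18
  to −1.2 mm (posterior) mid-thoracic, +0.4 mm low-thoracic and +1.5 mm
  (anterior) lumbar, following the developing sagittal profile; zero
  upper-thoracic.

The mid-thoracic height and CSA anchors are *jointly* calibrated so that
mean slenderness over ages 9–13 is 0.23 for females and 0.27 for males
(plateau heights 4.4/5.4 mm and CSA-at-age-11 of (H/S)² = 366/400 mm²).
The published descriptions are not mutually consistent here: males are
reported with marginally greater height and greater CSA everywhere, which
cannot coexist with the female slenderness being lower at equal scale.
The slenderness means are the quantitatively printed (and most
scrutinised) anchors, so they take precedence; the side effect is that
female mid-thoracic birth CSA slightly exceeds the male value before the
curves cross in early childhood.

### What the phantoms do and do not emulate

They reproduce the *statistical structure* used by the analyses: group-
and sex-specific scale trajectories, volume-ratio trends, nucleus-offset
drift, anisotropic voxels, patient pose, and per-disk noise. They do not
contain MR intensities (labels only — the manual thresholding step is
out of scope), vertebral bodies, endplates, degeneration, or realistic
disk outlines beyond a convex superellipse; segmentation error is a
voxel-level boundary-noise model, not an observer model. A passing
validation therefore demonstrates that the measurement chain is unbiased
and rotation-invariant on known geometry of realistic size and noise —
not that it handles pathological anatomy or real segmentation artifacts.

## Cohort statistics

- **Stratification**: level groups by index range; age groups infantile
  0–3, juvenile 4–10, adolescent 11–18, applied to floor(age) since the
  groups are defined in whole years.
- **LOESS**: tricube-weighted local polynomial (default degree 1, span
  0.75) over the span·n nearest neighbours, duplicate-x ties entering the
  window inclusively; arbitrary query points. A window covering the whole
  sample uses uniform weights, making span = 1 the global polynomial fit
  — the natural bandwidth → ∞ limit and the package's boundary
  convention. Growth-curve scatter points are per-subject means within a
  level group (one value per scan and group).
- **Percent change**: reported as final value as a percent of the
  initial LOESS value (460% = ×4.6; a flat curve is 100%). The
  alternative convention ((final−initial)/initial) differs by exactly 100
  points, so this choice is documented and tested, not assumed. Reading
  the birth value reliably needs a span that keeps the boundary window
  inside the steep infancy phase; the analysis uses span 0.35 for these
  reads.
- **Trend tests**: OLS of the outcome on age, optionally with a male
  indicator. (A "logistic regression on age" is not well-defined for
  continuous morphometric outcomes; the trend test is deliberately
  ordinary least squares and labelled as such.)
- **Sex comparison**: Welch's unequal-variance t test (group variances
  cannot be assumed equal).
- **Reliability**: ICC(2,1) — two-way random effects, absolute
  agreement, single measure — from the ANOVA mean squares, with
  F-distribution confidence bounds; the standard model for intra/inter-
  operator segmentation agreement. Degenerate inputs (one rater, zero
  total variance) raise errors; perfect agreement returns a collapsed CI.

## Numerical and design choices

- Overlapping AF/NP labels are an input error (label maps are disjoint by
  construction); after gap closing, which can brush the AF–NP interface,
  the NP keeps priority.
- Per-level measurement failures flag the row and never abort a cohort
  run; a failed sagittal-plane construction (fewer than three usable
  levels) falls back to the scanner-left normal and flags every row of
  that scan.
- All randomness flows from explicit seeds (`PhantomSpec.seed`,
  `RunConfig.seed`, per-function `rng`); re-running a scan with the same
  config is byte-identical.
- Validation problem sizes: the analytic oracles use one 15 × 10 × 8 mm
  cylinder; the rotation sweep spans rotations of 10–30° about each axis;
  parameter recovery regresses 100 mixed-age disks; the calibrated-anchor
  runs use 20 disks per age at 0.5 mm isotropic voxels. These sizes put
  the Monte-Carlo error of each check well below its tolerance.

## Known limitations

- The centroid-chord height of a strongly wedged disk differs from a
  footprint-averaged height; the phantom disks are untapered, so the
  validation does not probe that difference (the `mean` variant exists
  for such data).
- Nucleus offsets are reported signed per anatomical axis; voxel-centroid
  quantization limits their single-disk precision to ~0.1–0.15 mm at
  0.5 mm voxels.
- The exclusion filter trusts manifest flags; no image-based quality
  control is performed.
- Cohort summaries treat disks within a subject as independent within a
  level group apart from the per-subject averaging; no mixed-effects
  modelling of within-subject correlation is attempted.
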