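# Methods

This note documents the geometric model, the statistical procedures, the
synthetic-data generator, and the numerical and design choices behind the
`transsylvian` package.

## Coordinate frames

All geometry lives in a Talairach-style AC-PC frame: origin at the
anterior commissure (AC), x to the subject's right, y anterior, z
superior, units mm. The frame is fitted from three fiducials — AC, the
posterior commissure (PC), and any mid-sagittal point well off the AC-PC
line — as a **rigid** motion (rotation + translation): AC maps to the
origin, PC onto the negative y axis at its measured distance, and the
mid-sagittal point into the x = 0 plane with positive z. No scaling is
applied; whether classical piecewise Talairach scaling should follow is a
question the alignment deliberately leaves open, because all downstream
quantities are angles and ratios that scaling along a single axis would
distort but a rigid reorientation cannot.

Fiducial pairs closer than 1 mm (or a mid-sagittal point within 1 mm of
the AC-PC line) are rejected as annotation errors rather than propagated:
sub-voxel coincidence cannot be distinguished from a mis-click.

The chiasmatico-commissural (CH-PC) frame shares the x axis and is
pitched 18.2° about it, bringing the horizontal plane parallel to the
Sylvian fissure. The literature fixes the magnitude but not an explicit
sign convention for the rotation; we pitch the AC-PC horizontal
anterior-end-down (rotation about +x by −18.2°), since the optic chiasm
lies antero-inferior to AC. The choice is isolated in one function
(`coordinate_frames.chpc_rotation`) so it can be flipped wholesale. Note
that transferring a *mean* vector and averaging *per-subject transferred*
angles do not commute; the pipeline reports both orders side by side and
treats neither as canonical.

## Trajectory angles

The trajectory runs from the limen insulae (entry point of the
transsylvian dissection) to the target: the midpoint of the hippocampal
and innominate sulci on the coronal slice through the posterior edge of
the amygdala. The two sulcal landmarks must agree in y within 0.5 mm
(half a typical MPRAGE voxel) or the midpoint is refused — a larger gap
means they were placed on different coronal slices.

Left-hemisphere geometry is mirrored about the mid-sagittal plane
(x ↦ −x) before any angle is measured, so both sides share one
right-handed configuration and are directly comparable. With
d = target − origin after mirroring:

- axial angle  θa = atan2(−d_y, d_x)  (posterior positive),
- coronal angle θc = atan2(−d_z, d_x)  (inferior positive),

both in degrees. Under these signs the cohort means are positive and a
negative θc reads as "slightly superior". When |d_x| ≤ 0.1 mm the angle
is annotation-noise dominated and an error is raised instead of
returning ±90°; when d_x < 0 (target medial past the mirroring plane's
normal direction) the angle exceeds 90° and a warning is attached.

The sphenoid ridge is the line from an outer point near the pterion to
an inner point near the clinoid process. Its direction is undirected, so
the axial-plane angle against the x axis is folded into (−90°, 90°] with
the same posterior-positive sign. Parallelism between a trajectory and
the ridge is summarised by the signed offset θa − ridge and by the count
of trajectories with |offset| ≤ 10° (boundary inclusive — "within"
counts the boundary).

## Cohort statistics

Summaries are sample mean, sd (n−1 denominator), min, max, range.
Right-left asymmetry uses the two-sided paired t-test, pairing by
subject, significance at α = 0.01. The approach/ridge association is
reported as both Pearson and Spearman coefficients (with two-sided
p-values from the t approximation on n−2 df); Pearson is the default
headline. Both are always computed because the two are natural
alternatives for a 56-point angle sample and reports should not silently
prefer one.

## Synthetic cohort generator

Real landmark data cannot ship with the package, so cohorts are
simulated **at the angle level with inverse landmark construction**:
angles are sampled first, then landmarks are laid out to realise them
exactly. Noise enters only through anchor positions (limen, ridge
anchor), which every angle is invariant to, so the latent truth is
recoverable to machine precision (the suite checks 1e-6°). This
separates generator calibration from pipeline correctness: a measurement
bug cannot hide inside generator noise.

Study-profile defaults (degrees unless noted):

| parameter | default | origin |
|---|---|---|
| n_subjects | 28 (bilateral) | study cohort size |
| axial mean right / left | 54.6 / 50.2 | reported side means |
| coronal mean right / left | 17.0 / 15.5 | reported side means |
| ridge mean / sd | 49.7 / 3.5 | reported ridge statistics |
| pooled axial–ridge correlation | 0.462 | reported correlation |
| axial sd | 6.5 | calibrated, see below |
| coronal sd | 10.0 | calibrated, see below |
| interhemispheric correlation | 0.58 | calibrated, see below |
| limen (right) | (33, 6, −14) mm | atlas-plausible placeholder |
| left limen offset (Δy, Δz) | (−2, −2) mm | postero-inferior shift, direction reported, magnitude assumed |
| landmark noise sd | 1.0 mm | typical manual placement error |
| approach Δx | 8.0 mm | see below |
| n_tle | 12 | validation cohort size |

Calibrations:

- **axial sd 6.5 / coronal sd 10.0.** For a normal sample of n = 56 the
  expected range is ≈ 4.66 sd; 6.5° and 10.0° reproduce the reported
  ranges (34.2° axial, 48.6° coronal) and, together with ridge sd 3.5°,
  correlation 0.462 and mean offset 2.7°, give
  P(|θa − ridge| ≤ 10°) ≈ 0.89, matching the reported 50/56.
- **interhemispheric correlation 0.58.** The reported paired tests
  constrain the *paired-difference* sd, not just the marginals: the
  coronal test (difference 1.5°, p = 0.392, n = 28) implies a paired sd
  ≈ 9.2°, i.e. 2(1−ρ)·σc² with ρ ≈ 0.58; independent hemispheres
  (ρ = 0) would also make the reported axial difference of 4.4°
  non-significant, contradicting its p < 0.01. The same ρ is applied to
  both planes and the ridge via a shared subject-level component plus
  side-level residuals; marginal sds and within-side cross-correlation
  are unchanged by this decomposition.
- **pooled-correlation calibration.** The reported r = 0.462 describes
  all 56 trajectories pooled. Pooling adds the between-side mean split
  (±2.2°) to θa's variance but not the ridge's, so the within-side
  correlation is set to 0.462·√(6.5² + 2.2²)/6.5 ≈ 0.488, which makes
  the *pooled* expectation 0.462.
- **approach Δx 8 mm.** The adjacent-side length that turns the mean
  angles (52.4°, 16.2°) into the mean displacement ≈ (8, −10.4, −2.3) mm.
  The generator places the target at limen + (Δx, −Δx·tanθa, −Δx·tanθc)
  in mirrored coordinates — the exact inverse of the measurement.
- Sampled |θa| (and |θc|) are capped at 89° so the inverse construction
  stays clear of the 90° projection degeneracy; at the default sds the
  cap is ~5σ out and effectively never binds.

What the generator does **not** emulate: real landmark identifiability
(slice selection for the limen and amygdala are not modelled), scanner
geometry and intensity data, non-isotropic or rater-dependent placement
error, and any anatomical covariance beyond the angle structure above.
Passing tests therefore certify the measurement/statistics machinery and
the internal consistency of the study profile — not agreement with any
particular patient population.

## Ventricle simulation

The validation question — does a ray from the limen insulae along the
standard angles (52.4° posterior, 16.2° inferior) enter the inferior
horn? — is answered by explicit ray casting into a binary mask: samples
every 0.25 mm (≪ voxel size) out to 60 mm (comfortably beyond the
limen-to-horn distance), nearest-voxel lookup, first foreground contact
wins. An exhaustive voxel-traversal oracle checks the axis-aligned
cases in the suite.

Synthetic horns are tube phantoms: a cubic-spline centerline voxelised
as a union of capped cylinders (no spherical end caps, so a straight
tube matches the analytic πr²L volume; voxels containing centerline
samples are always kept, so sub-voxel radii still leave a traceable
track). Radius 2.5 mm for the control profile, 3.5 mm for the TLE
profile (atrophic enlargement). For left-sided subjects the voxel grid
is mirrored and its affine re-anchored, so left and right masks are
voxel-for-voxel mirror images.

The default centerline passes through each subject's own trajectory
target — the phantom is anchored to per-subject anatomy, not to the
standard vector — running from the temporal-tip region anteriorly and
rising posterosuperiorly toward the atrium. Its control-point offsets
are engineering defaults chosen, by a design-stage geometric study of
ray-tube miss distances under the study-profile angle distributions, so
that a correctly implemented standard vector reliably reaches the
phantom (per-subject miss probability well under 1%), as the trajectory
did in the study's patients. They are not measured anatomy.

## Problem sizes and runtime

The replicate-averaged recovery experiment uses 10 independent cohorts
of 28 subjects (56 trajectories each), with per-cohort seeds spawned
from one master seed via `derive_cohort_seeds`; the simulation stage
uses 12 TLE subjects at 1 mm voxels. The full test suite runs in well
under a minute on one CPU; the acceptance script in a few seconds.

## Known limitations

- The CH-PC rotation sign and the order of averaging vs transfer are
  genuinely underdetermined; CH-PC outputs are reported both ways and
  should be read with that caveat.
- The ±10° parallelism boundary is counted inclusively; a strict reading
  would change counts only for offsets exactly at the boundary.
- Landmark input is world- or AC-PC-frame mm only; voxel-index input is
  out of scope.
- The horn phantom is a constant-radius tube; real inferior horns are
  slit-like anteriorly and widen posteriorly, so absolute entry
  distances should not be over-interpreted.
- The sample Pearson r of a 56-trajectory cohort has sd ≈ 0.13; even a
  10-cohort average carries ≈ 0.04 of Monte Carlo spread around the
  configured 0.462.
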