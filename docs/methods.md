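# Methods

`infatlas` builds longitudinal infant brain atlases — per age group a
grayscale **template**, CSF/GM/WM **tissue probability maps** (TPMs) and an
anatomical **parcellation**, plus averaged **cross-age correspondences**
linking the three atlas spaces — and evaluates them in the three ways
atlases are consumed. This note documents the models, the synthetic cohort
they are exercised on, the numerical choices, and the limitations.

## The three-step construction

**Step 1 — longitudinal tissue segmentation.** The anatomically mature
2-year image of each subject is segmented by adaptive fuzzy c-means
(AFCM): the fuzzy c-means objective `Σ_k Σ_x u_k(x)^m (y(x) − g(x) c_k)²`
with fuzziness `m = 2` is minimised by alternating exact membership and
centroid updates with a smooth multiplicative gain estimate `g` (a
wide-Gaussian-smoothed log-residual, normalised to geometric mean 1; the
gain update is only accepted when it lowers the objective, so the
recorded objective sequence is non-increasing). Classes are identified by
ascending centroid order under a configurable, age-appropriate contrast
convention (CSF < GM < WM for T1-like images; GM < WM < CSF for T2-like
neonatal contrast).

The low-contrast earlier timepoints are segmented by EM on a
spatially-weighted Gaussian mixture: the class posterior is proportional
to a relaxed prior times a per-class Gaussian mixture likelihood, with the
relaxed prior `(1 − λ)·prior + λ·uniform` (`prior_relax` λ, default 0.3
inside the longitudinal loop). Multiple components per class let one "WM"
class cover both myelinated and unmyelinated white matter in the neonate
(default two WM components at age 0). The EM log-likelihood is
non-decreasing; variances carry a relative floor of `1e-4 · var(y)`.

`joint_longitudinal_segment` ties the two together: the age-2 image is
affine-registered to the early image on intensities, its segmentation
warped across, the early image segmented with those priors, and the loop
then alternates deformable registration of the (segmented) mature image
onto the current early segmentation with re-segmentation under the warped
TPMs, stopping when consecutive early segmentations agree to `dice_tol`
(default 1e-3, `max_outer` 5). Registrations run on segmentations, not
intensities, because the intensity profile changes drastically across
these ages. On the phantoms below, where the cross-age change is largely
captured by the affine plus the intensity model, the loop's deformable
refinement is marginal; it is guaranteed not to lower its own overlap
measure, and the suite asserts it stays within 0.005 Dice of the
affine-initialised solution while exceeding 0.9 against ground truth.

**Step 2 — anatomical labeling.** A donor parcellation reaches each
subject through the subject's own age-2 image as a *bridge*: donor
segmentation → deformable registration onto the bridge segmentation →
nearest-neighbour warp of the label volume, then propagation to ages 0
and 1 with the longitudinal fields from step 1. Per age group the
per-subject parcellations are fused in the common space by voxel-wise
plurality voting (ties to the smallest label id; background votes as
label 0). The package ships a 116-region AAL-compatible label table (45
cerebral volumes of interest per hemisphere, cerebellar hemispheres and
vermis) as metadata; phantom runs use generated angular parcels, and no
donor MRI volume is distributed.

**Step 3 — unbiased groupwise registration.** All subjects of one age
group are aligned to a hidden common space: a deterministic reference is
chosen (minimum summed SSD over coarse pairwise affine alignments),
everyone is affine-aligned to it, and the loop then (a) averages the
warped TPMs/intensities, (b) deformably registers each subject to the
mean segmentation, and (c) removes the common mode by composing every
field with the inverse of the voxelwise mean field, driving the average
displacement toward zero (the unbiasedness contract; final mean below
0.25 voxel on test cohorts). Subjects are processed in a canonical
content-hash order internally, so permuting the input order permutes only
the outputs. Atlases are voxelwise means of the aligned images, TPMs
renormalised to sum to one in the mask, parcellation fused by vote.

**Cross-age correspondences.** With `compose(f, g)` defined so that its
point map is `T_f ∘ T_g` (`T_u(x) = x + u(x)`, pull-back fields on the
fixed grid), the per-subject atlas(i)→atlas(j) chain is
`Φ_s = compose(invert(g_j), compose(f_s^{i→j}, g_i))`, where `f_s^{i→j}`
warps the age-j image into age-i space and `g_s` warps the subject into
its atlas space; `Φ` is averaged voxelwise over subjects. The chain
direction is a convention fixed by two tests: pure-scaling growth is
recovered, and `Φ(0→1)` chained with `Φ(1→2)` agrees with `Φ(0→2)` to
under a voxel.

## Pairwise registration machinery

*Affine*: 12 parameters (translation/rotation/log-scale/shear about the
grid centre), Powell minimisation of `1 − |masked Pearson correlation|`
over a coarse-to-fine pyramid with soft parameter bounds. Correlation
rather than raw SSD makes cross-contrast longitudinal pairs (T2-like
neonate vs T1-like 2-year-old) well-posed; for same-contrast images it is
SSD after the optimal linear intensity map. `maxiter` also caps Powell's
function-evaluation budget (30 per iteration), the main runtime knob.

*Deformable*: HAMMER-style attribute matching on segmented images. Per
voxel the attribute vector holds a membership-weighted pseudo-intensity,
a categorical boundary type (CSF–GM, GM–WM, CSF–WM, brain–background,
from the 6-neighbourhood of hard labels) and per-tissue geometric moment
invariants — mass, trace, second invariant and determinant of the centred
second-moment tensor of the class membership in a spherical neighbourhood
(radius 2 voxels by default); continuous channels are z-scored over the
mask, and the moment invariants commute exactly with 90° grid rotations.
Driving voxels are boundary voxels ranked by the GMI norm, kept at a
minimum spacing of 2 voxels by greedy suppression. Each driving voxel
searches the fixed image within the level's radius for candidates of the
same boundary type, ranked by feature similarity `exp(−½·mean(ΔF²))`
times a Gaussian distance prior (scale radius/2 — small displacements win
among equally similar boundary voxels); the target is the unweighted mean
of the near-tie candidates (within 95% of the best score, at most `k`),
per-pair confidence the mean similarity. Updates are densified by 3-D
thin-plate splines (kernel `U(r) = r`, affine part, ridge
`1e-3 ×` median control spacing; intermediate updates are evaluated on a
stride-2 subgrid and trilinearly upsampled, then smoothed by 3 mm),
composed into the accumulated field, and **rejected if the mean per-class
Dice against the fixed segmentation would drop** — so overlap is monotone
over accepted updates. Default schedule: search radius 4→2→1 voxels,
driving fraction 0.2, 2 iterations per level. On shell-like phantom
anatomy the boundary features suffer a strong aperture ambiguity
(tangential matches are nearly equivalent), which bounds how much of a
random smooth field the matcher can recover; the acceptance study checks
that it still beats the affine baseline on both Dice and residual error.

*DCT normalisation* (evaluation protocol): subject and template are
smoothed with the **same** kernel (matching their fuzziness; fitting a
smoothed subject to a sharp few-subject template destabilises the fit
around thin bright structures), affine-aligned, and the residual
displacement is expanded in the lowest `basis_dims` separable DCT-II
cosine modes per direction (7×8×7 at full protocol scale = 1176
coefficients; 4³ at desk scale). Coefficients minimise SSD plus an
`reg_weight`-scaled squared-coefficient penalty by L-BFGS-B with the
analytic image-gradient Jacobian, coarse-to-fine in image smoothness
(extra σ = 2 then 0 voxels) with warm starts, restarting on line-search
failures (the trilinear objective has gradient kinks at integer
coordinates). Sampling uses clamped (nearest) boundaries — constant
padding makes the objective discontinuous across boundary planes.

*Field algebra*: `compose` by trilinear lookup, fixed-point `invert`
(`g ← −f(x+g(x))`, raising with the residual attached if the composed
residual exceeds 0.5 voxel — evaluation experiments use best-effort
inversion so that a barely-invertible fit surfaces as low Dice instead of
an abort), voxelwise `mean_field`, and `warp` with trilinear interpolation
for intensities/probabilities (renormalised in-mask) and nearest-neighbour
for labels.

## The phantom cohort

The generator emulates the structure of a longitudinal infant cohort, not
MR physics. A shared base anatomy (concentric CSF/GM/WM shells with
sinusoidal angular perturbations as sulcus/gyrus analogues, plus angular
parcels and a central "myelinated" WM core) is warped per subject by a
smooth random field (`deform_amplitude_mm`, default 3 mm at max, 8 mm
smoothness, min Jacobian determinant kept above 0.1). Earlier ages derive
from the subject's age-2 anatomy by isotropic shrinkage about the grid
centre (linear growth factors 0.82/0.96/1.0, following the reported
volume trajectory: roughly half the mature volume at birth, ≈90% of adult
volume by age two) **plus an age-specific smooth non-uniform growth
component** proportional to the deformation amplitude — real brain growth
is spatially non-uniform, and with a purely affine cross-age truth the
longitudinal registration tasks would be trivially solved by the affine
step. Setting the amplitude to zero recovers pure scaling, for which the
mean true displacement has the closed form `(ratio − 1)·E|x−c|`. The true
age→2 fields are closed-form; the remaining pairs follow by numerical
field algebra, and the generator's self-consistency (forward∘backward
residual < 0.25 voxel) is asserted in the suite.

Intensities are piecewise-constant class means with a smooth multiplicative
bias field (amplitude 0.2) and additive Gaussian noise (σ 6). Age 0 is
T2-like with deliberately poor contrast — CSF 180, GM 115, WM split 135
(unmyelinated, the bright majority) / 90 (myelinated core) — because poor
neonatal contrast with an ambiguous intensity distribution is precisely
the condition that makes prior-guided segmentation necessary; age 1 is
T1-like with reduced contrast (45/100/120), age 2 near-adult T1
(40/100/145). These are configuration defaults, not claims about real MR
units.

What the phantoms do **not** model: cortical folding geometry (the
sinusoidal shells have far less boundary structure than a real cortex,
which is why feature matching is aperture-limited here), partial-volume
mixing, skull/dura (masking is nearly trivial), scanner physics, and
non-Gaussian intensity distributions. Passing tests therefore demonstrate
the correctness and internal consistency of the machinery and the
direction of the comparative effects, not clinical-grade accuracy on real
infant MRI.

## Evaluation experiments

Held-out subjects (not used in construction) are processed against
age-matched and age-mismatched bundles: (1) **spatial normalisation** —
subjects are DCT-normalised to each template, their tissue maps warped
along, a voxel-wise majority-voted structure image formed per atlas, and
per-subject per-class Dice against the vote measures stacking
consistency; (2) **label propagation** — each bundle's parcellation is
carried to every age of every subject via the inverse of the
subject→template fit, maps are compared across age pairs (0v1, 0v2, 1v2)
after routing through the averaged cross-age correspondences; (3)
**neonatal segmentation** — bundle TPMs are warped to each neonate and
used as EM priors, scored against ground truth. Atlas contrasts use
paired two-sided t-tests across subjects at α = 0.05 (no multiplicity
correction by default; Holm behind a flag), recorded in the output
metadata. Age-mismatched bundles emulate the role of older-population
control atlases.

## Problem sizes and defaults

Desk-scale defaults: 32³–48³ grids at 1.5–2 mm, cohorts of 4–10 subjects,
5 cohort seeds for the comparative studies, DCT basis 4³ and 4 mm
protocol smoothing (about half the full-scale 8 mm kernel, matching the
roughly threefold smaller phantom brains), bias-estimation σ 20 mm
(tracking the phantom bias correlation length; full-scale images would
use larger). The packaged full-resolution atlas space is 181×217×180 at
1 mm with the anterior commissure at voxel (90, 126, 72) (0-based; the
world origin lands exactly on that voxel). Voxel indices are 0-based,
world coordinates in mm on RAS-like axes; displacement fields are stored
as 4-D NIfTI with 3 mm-valued components along the world axes; label
volumes are unsigned integers with a TSV sidecar.

## Known limitations

- The deformable matcher recovers the normal component of boundary motion
  well but is aperture-limited tangentially on smooth shell anatomy;
  residual-error reductions are modest even when overlap gains are large.
- The joint longitudinal loop adds little beyond its affine+EM
  initialisation on these phantoms (see above); its value is expected on
  anatomies with strong non-affine, feature-rich cross-age change.
- Under the Gaussian phantom intensity model, a single free-variance WM
  Gaussian is a robust "broad net": the two-component WM model wins
  decisively on log-likelihood (≈ +350–400 at 32³) and is the correct
  generative description, but does not beat the single-component model on
  Dice in any regime we measured. The suite asserts the likelihood
  ordering and the bracketing of GM by the two fitted WM means.
- Field inversion is fixed-point and assumes displacement gradients below
  one; expansive growth maps clamped at the grid boundary leave small
  residuals there, which is why generator self-consistency is asserted as
  a mean over the grid.
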