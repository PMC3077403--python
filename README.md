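# infatlas

Longitudinal infant (0–1–2 year) brain atlas construction and evaluation
at desk scale, exercised end-to-end on synthetic brain phantoms with
known ground truth.

## The problem

Infant neuroimaging needs age-specific atlases. The brain roughly doubles
in volume over the first two years, white matter myelinates (so its MR
intensity profile changes drastically, and most neonatal WM is
unmyelinated), and neonatal images have poor tissue contrast — so an
adult or even a pediatric atlas misrepresents infant anatomy for the
three standard atlas applications: spatial normalisation (template),
tissue segmentation (CSF/GM/WM probability maps, "TPMs"), and anatomical
labeling (a parcellation map). This package implements a three-step
construction of consistent atlases for neonates, 1-year-olds and
2-year-olds from one longitudinal cohort, plus the averaged cross-age
correspondences linking the three atlas spaces:

1. **Longitudinal tissue segmentation** — the easy, early-adult-like
   2-year image is segmented by adaptive fuzzy c-means (AFCM, fuzzy
   memberships `u_k` with a smooth multiplicative gain field); the hard,
   low-contrast earlier images are segmented by EM on a prior-weighted
   Gaussian mixture, `P(k|y,x) ∝ π_k(x) Σ_c w_kc N(y; μ_kc, σ²_kc)`,
   with the subject's own warped 2-year TPMs as priors `π_k` and two WM
   components covering myelinated/unmyelinated white matter. Registration
   and segmentation iterate, yielding the cross-age deformation fields.
2. **Anatomical labeling** — a donor parcellation is registered to each
   subject's 2-year image (the *bridge*), propagated to ages 0/1 with the
   longitudinal fields, and fused across subjects by voxel-wise majority
   voting. A 116-region AAL-compatible label table (45 cerebral VOIs per
   hemisphere plus cerebellum/vermis) ships with the package.
3. **Unbiased groupwise registration** — all subjects of an age group are
   registered simultaneously to a hidden common space (attribute vectors
   on segmented images: intensity, boundary type, geometric moment
   invariants; driving voxels; thin-plate-spline densification,
   `U(r) = r`), with the mean deformation explicitly driven to zero so no
   subject biases the atlas. Templates/TPMs are voxelwise averages;
   parcellations are fused by vote. Cross-age correspondences are
   per-subject compositions `Φ_s = g_j⁻¹ ∘ f_s^{i→j} ∘ g_i`, averaged
   over subjects.

Evaluation mirrors atlas use: spatial normalisation consistency against a
majority-voted structure image (Dice ratio `DR = 2|A∩B|/(|A|+|B|)`),
cross-age label-propagation consistency, and TPM-guided neonatal
segmentation accuracy — each comparing age-matched against age-mismatched
atlases with paired t-tests.

Because no public infant cohort is bundled, a first-class **phantom
generator** produces longitudinal cohorts (per-subject anatomy; growth =
isotropic scaling plus a non-uniform component; T2-like neonatal contrast
with bimodal WM; bias field; noise) whose tissue labels, parcellations
and cross-age deformation fields are known exactly — so every stage can
be scored against ground truth.

## Worked example

`examples/02_longitudinal_segmentation.py` runs step 1 on one phantom
subject (32³ grid, 2 mm):

```
age 0: masked 4939 voxels, estimated gain range 0.94-1.06
age 2: masked 8840 voxels, estimated gain range 0.87-1.15
age-2 AFCM Dice (CSF/GM/WM): [1.0, 1.0, 1.0]
age-0 joint-loop Dice (CSF/GM/WM): [0.95, 0.98, 0.929]
fitted neonatal WM mixture (weight, mean): [(0.22, 79.1), (0.78, 129.2)]
late->early field mean displacement: 7.5 mm
```

Reading: bias correction recovers a multiplicative gain near 1; the
mature timepoint segments essentially perfectly; the low-contrast
neonatal image still reaches ≥0.93 Dice per class because the subject's
own warped 2-year tissue maps guide it; and the fitted WM mixture
separates the dark myelinated core (mean ≈ 79, weight 0.22) from the
bright unmyelinated majority (≈ 129) — the two-population WM model at
work. The other examples generate cohorts, recover known deformations,
build the three atlas bundles with their cross-age correspondences, and
reproduce the age-matched-beats-mismatched comparisons
(`examples/05_evaluate_atlases.py`).

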