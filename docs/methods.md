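# Methods

This note documents the models, conventions and design choices behind
`scarpipe`, in the order the pipeline runs.

## Synthetic left-ventricle phantom

**Geometry.** The LV is a truncated half-ellipsoid shell: endocardial
surface x²/a² + y²/a² + z²/c² = 1 (z ≤ 0) with a = `endo_radius` (20 mm)
and c = `lv_length − wall` (wall = `epi_radius − endo_radius`, 10 mm);
epicardium likewise with `epi_radius` (30 mm) and `lv_length` (90 mm). The
base plane is z = 0, the apex at z = −`lv_length`. Partial volumes of the
shell are analytic (∫ πr(z)² dz), so scar-fraction ground truths are exact.

**Scar.** A contiguous transmural wedge: an azimuthal interval crossed with
an axial band (default 25–75% of depth below the base). The per-patient
scar volume fraction is drawn from `scar_fraction_range` (default
0.05–0.20) and the wedge angle is solved analytically to hit it. The wedge
is emitted as a watertight surface mesh (six structured patches with shared
boundary vertices) and as a voxel label grid; the two agree to Dice > 0.95.

**Misalignment.** The "MRI" copies of the meshes are the CT meshes mapped
through the inverse of a random rigid transform (rotation up to 12° about
the shell centroid plus translation up to 8 mm by default) with isotropic
Gaussian vertex noise, sd 0.5 mm — enough that ICP must do real work but
small against the 10 mm wall. RV-insertion landmarks sit on the epicardium
120° apart near the base and are mapped exactly.

**Intensities.** Voxel grids (1 mm isotropic, enclosing the LV) contain
blood pool, myocardium (80 HU) and scar, with scar enhanced by
`scar_mean_shift` (25 HU) times a per-energy contrast scale. Two energies
are emitted: 80 kV (contrast scale 1.25, noise sd 25 HU) and 100 kV
(scale 1.0, sd 15 HU) — the lower tube voltage shows more iodine contrast
at the price of noise. Scar noise is spatially smoothed (Gaussian,
correlation length 1.5 mm) and amplitude-reduced, so the discretized
gray-level diversity inside scar is strictly lower than in remote
myocardium; this is the dominant signal the analysis is built to detect.

Three further sources of variability emulate what makes real cohorts hard,
and they decide *which* features screen to the top:

* `patient_hu_sd` (12 HU): a per-patient global enhancement offset
  (contrast timing, habitus). It makes absolute intensity-location features
  (mean, median, percentiles) unreliable across patients.
* `patient_noise_scale_range` (0.75–1.3): per-patient noise amplitude
  (automatic tube-current modulation). It makes absolute spread features
  (IQR, MAD) unreliable.
* `scar_noise_scale_range` (0.55–0.9) and `scar_heterogeneity` (0.35, a
  smooth axial modulation of the scar noise amplitude): between- and
  within-patient variation of infarct texture. It desaturates the
  normalized texture features per slice.

What survives all three is the *systematic* structure: the scar region is
smaller and more homogeneous than the remote myocardium on every slice, so
the unnormalized non-uniformity features (GLDM/GLSZM/GLRLM gray-level,
dependence, size-zone and run-length non-uniformity) and the energy
features dominate the screening — the hierarchy the method targets on real
data. With these dials at zero the phantom is still valid but nearly every
feature separates perfectly and the ranking loses meaning.

**What the phantom does not emulate:** CT physics (beam hardening, motion,
partial volume), non-transmural or multifocal scar, papillary muscles and
trabeculation, atlas-level anatomical variation, and segmentation error
beyond mesh vertex noise. Passing tests therefore demonstrate that the
pipeline recovers engineered signals of realistic size and structure — not
clinical performance.

## Three-step rigid registration

Point-to-point ICP with nearest-vertex correspondences (k-d tree) and the
closed-form Kabsch update; no scaling, no outlier trimming by default
(a `trim_fraction` is available). Initialization is the composition of
(1) the minimal rotation aligning the endocardial principal axes plus the
centroid translation, and (2) the rotation about the long axis that best
matches the projected RV insertion points (2D Procrustes angle). The
principal axis sign (base → apex) uses the `apex` landmark when present and
otherwise a pointedness heuristic: the apex end of an LV shell has the
smaller mean radial spread. Defaults: `max_iter` 100, `tol` 1e-4 mm on the
RMS correspondence distance, which is monotone non-increasing by
construction. Manual visual QC is replaced by an automatic check on
post-registration apex and base-centroid distances (5 mm thresholds).

## Short-axis slicing and the transmural rule

60 planes are spread evenly between the basal and apical extent of the
endocardium along its principal axis, inset by half a spacing. Mesh–plane
cross-sections are closed by angular ordering (valid for the star-shaped
contours of LV shells) and pixels are classified with 2D point-in-polygon
tests (1 mm pixels; the in-plane u axis points at the anterior RV insertion
when available). Scar membership is angular: the scar cross-section's
angular footprint about the ring centre is swept across the full wall, so
partial-thickness scar labels the whole wall at those angles. A slice is
valid for paired analysis when its non-scar myocardium has ≥ 16 pixels;
scar-region features are computed only when the scar region also has ≥ 16
pixels (texture matrices on smaller regions are mostly noise). Intensity
sampling is nearest-voxel on the single slice plane; slab averaging is not
implemented.

## Radiomic features

93 features: 18 first-order, 24 GLCM, 14 GLDM, 16 GLSZM, 16 GLRLM,
5 NGTDM — the default-enabled sets of the common open-source feature
definitions. Conventions, fixed so the brute-force oracles in `tests/`
can reproduce every value exactly:

* fixed-bin-width discretization, default 5 HU, anchored at the region
  minimum (`level = ⌊(x − min)/bin_width⌋ + 1`);
* 2D computation with four offsets/directions (0°, 45°, 90°, 135°) for
  GLCM/GLRLM, 8-connectivity for GLDM/GLSZM/NGTDM;
* GLCM symmetrized; co-occurrence and run matrices summed over
  offsets/directions *before* feature computation; run percentage divides
  by pixels × directions;
* GLDM dependence = number of 8-neighbours within `alpha` (default 0) gray
  levels; the matrix column index is dependence + 1;
* NGTDM coarseness capped at 1e6 when Σ pᵢsᵢ = 0;
* degenerate features (correlation, IMC1/2, MCC at a single gray level;
  skewness/kurtosis of a constant region) are returned as NaN and flagged
  in `FeatureVector.undefined`, then imputed with the cohort median before
  any statistics;
* multi-slice (segment) regions share one bin anchor (pooled minimum),
  texture matrices are computed per slice and summed, first-order
  statistics use the pooled samples.

Total energy multiplies energy by a `pixel_volume` (default 1 mm³ per
pixel); it is a constant scale within an analysis.

## Screening

Per feature: a two-sided pooled-variance Student's *t*-test
(scar vs. non-scar region values; α = 0.05, no multiple-testing correction
by default, Benjamini–Hochberg behind a flag) and a cross-validated AUC.
Folds are split by patient — no patient straddles a fold — and stratified
on the quantile of each patient's scar-row prevalence. A univariate linear
regression of the label on the feature is fitted per training set; since a
monotone score enters the ROC only through ranks, the pooled out-of-fold
score is the feature itself under the orientation the training regressions
vote for (majority slope sign, applied globally so scores pooled across
folds stay comparable — per-fold sign/scale mixing otherwise inflates the
variance of the pooled AUC and mis-calibrates its CI). The 95% CI is a
percentile bootstrap over 1,000 resamples of the pooled (score, label)
pairs. The top-10 selection sorts by AUC, breaking ties by smaller
*t*-test p-value — computed in log space so that extremely significant
features are not tied at an underflowed 0.0 — then name.

## Combined energy

The 100 kV volume is registered rigidly to the 80 kV volume (mean-squared
error metric, regular-step gradient descent, linear interpolation, three
resolution levels) starting from identity: same-session volumes share a
frame, and identity initialization lets genuinely non-overlapping fields
fail loudly instead of being silently re-centred. Resampling fills
out-of-field voxels with −1024 HU. The combination is the convex voxelwise
mix `w·high + (1 − w)·low` on the low-energy grid — percentage
contributions imply weights summing to 1; a raw sum would double the HU
scale. For independent noise fields the w = 0.5 mix has sd
√(0.25σ₈₀² + 0.25σ₁₀₀²), below the noisier input.

## AHA 16 segments and classification

Thirds along the long axis are taken by slice index (basal 0–19, mid
20–39, apical 40–59 of 60); basal and mid rings split into six 60°
sectors and the apical ring into four 90° sectors whose centres align with
the anterior/septal/inferior/lateral walls. Angles are measured from the
anterior RV insertion, increasing toward the septum (direction fixed by the
inferior insertion when available). Apex-cap slices — planes beyond the
endocardial apex, with no cavity — are left unassigned, which drops the
17th segment. Segment scar fraction is scar pixels over myocardium pixels
(the constant pixel volume cancels); labels are fraction ≥ threshold for
thresholds 10/20/30%.

The top-10 features are recomputed on each segment's full myocardial
region (scar + non-scar pixels pooled across its slices), because the
ground truth is segment-level. Columns are scaled to unit Euclidean norm
using training rows only; zero-norm columns are flagged and zeroed.
Classifiers: SVM (C ∈ {0.1, 1, 10} × {linear, rbf}), logistic regression
(C ∈ {0.1, 1, 10}), random forest (100/300 trees × depth ∞/8). The inner
grid search uses plain accuracy: ROC AUC saturates on well-separated data
and ties resolve arbitrarily, which can select a degenerate operating
point. Outer evaluation is patient-wise 5-fold CV with pooled out-of-fold
decision scores (SVM margin, logistic probability, forest vote fraction);
AUC gets the same 1,000-resample percentile bootstrap CI; sensitivity and
specificity are read at each classifier's native threshold (0 margin /
0.5 probability / majority vote) since no operating-point rule is imposed.
Permutation importance shuffles each feature column of the test fold
(default 10 repeats, seeded) and reports the mean balanced-accuracy drop,
averaged over folds.

## Problem sizes and determinism

Default analysis sizes — 15 patients, 60 slices, 1 mm grids, 1,000
bootstrap resamples, 50-case registration sweeps — were chosen so the full
test suite and the acceptance script each run in minutes on a single CPU
while keeping texture matrices well populated and the statistics stable.
Every stochastic component (phantom draws, fold assignment, bootstraps,
permutation importance, classifier seeds) is driven by explicit integer
seeds; rerunning any entry point with the same seed reproduces its output
bit-for-bit.

## Known limitations

Rigid registration only (no deformable refinement, no cardiac-phase
matching beyond the transmural rule); single-plane nearest-voxel sampling;
2D texture only (no 3D matrices, filtered images or shape features);
per-slice feature rows are treated as independent within the t-test, as in
the source procedure, although slices within a patient are correlated —
the patient-wise CV protects the AUC ranking but not the raw p-values; the
phantom's simplifications listed above.
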