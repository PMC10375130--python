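# Methods

This note documents the models, conventions and numerical choices
behind `srmc`, in the order the pipeline applies them.

## Imaging model and spectral unmixing

A field of view is three co-registered 400×400 intensity images
(default 0.25 µm/px, i.e. a 100×100 µm field): a lipid channel at the
CH₂ stretch (2850 cm⁻¹), a protein channel at the CH₃ stretch
(2930 cm⁻¹), and a DNA channel at the CH₃ antisymmetric stretch
(2965 cm⁻¹). Detector units are arbitrary; all intensity features are
therefore only comparable within a consistently calibrated cohort.

Because the lipid and protein bands overlap, detector signals
(S_L, S_P) are converted to chemical concentrations (C_L, C_P) by a
fixed 2×2 linear unmixing

    [C_L]   [ 1.28583  −0.32401] [S_L]
    [C_P] = [−0.13406   1.28583] [S_P]

with coefficients calibrated on pure oil (lipid) and BSA (protein).
Negative unmixed values are kept, not clipped: they flag calibration
mismatch and average out in mask means. The DNA channel is used
geometrically only and is never unmixed.

## Segmentation

*Cells* are segmented from the DNA channel. The built-in baseline is
classical: Gaussian smoothing (σ = 2 px), foreground by the lowest of
the three-class multi-Otsu thresholds (cells are brighter than
background but dimmer than their nuclei, so plain Otsu would keep only
nuclei), hole/small-object cleanup (min area 50 px), Euclidean
distance transform smoothed at σ = 2 px, peak markers at minimum
separation 12 px, and marker-controlled watershed. A pre-trained deep
model can be registered as a plug-in backend behind the same contract;
asking for an unregistered backend is an explicit capability error.
Regions touching the frame border are kept but flagged.

*Nuclei* are found per cell by Otsu thresholding of the DNA-specific
image (DNA − α·lipid, α = 0 by default) restricted to the cell mask;
the largest component is kept and inherits the cell label. A cell
whose DNA signal is flat gets an empty nucleus and a flag — an
outcome, not an error.

*Lipid droplets* are bright foci of the unmixed C_L image. One
threshold per image — the 98th percentile of C_L over all within-cell
pixels — selects candidate pixels; connected components of ≥ 2 px
become droplets and are assigned to the cell containing their
centroid. The percentile is a parameter: it implicitly assumes LD
pixels occupy less than (100 − p)% of the within-cell area, and
should be lowered for LD-rich material.

Segmentation is scored by Dice = 2|A∩B|/(|A|+|B|) and IoU = |A∩B|/|A∪B|
on binarized masks (both defined as 1.0 when both masks are empty, an
agreement convention), and by the cell-counting RMSE
√(mean((n_pred − n_true)²)) with two relative variants: per-frame
relative percent (each difference divided by its true count) and
pooled percent (RMSE over the mean true count). The literature is
ambiguous about which relative form is meant by "RRSE"; both are
reported.

## The 19 single-cell features

Ten morphology features from the cell and nucleus masks: area (px²),
eccentricity, major/minor axis length (px, from the second central
moments of the region, i.e. the best-fitting ellipse), perimeter (px),
solidity (area over convex-hull area), circularity = 4π·area/perimeter²,
roundness = 4·area/(π·major²), cytoplasm area (cell minus nucleus,
px²) and cytoplasm area fraction.

Two conventions deserve emphasis:

* **Eccentricity here is minor/major** — the axis-length ratio, 1 for
  a circle and → 0 for a needle — *not* the conic-section
  eccentricity. This matches the measurement convention this pipeline
  reproduces and is kept deliberately.
* **Perimeter** defaults to the exposed pixel-edge count, which is
  exact for axis-aligned rectangles (4·side) and has the exact digital
  closed form 8r for rasterized discs; these exact values anchor the
  formula tests. Crofton and Freeman-weighted contour estimators are
  available as options. Circularity is strongly estimator-dependent
  (a digital disc scores π²/16 ≈ 0.62 under the default, ≈ 1.01 under
  Crofton), so circularities are comparable only within one estimator.

Nine composition features from C_L/C_P under three masks: lipid and
protein intensity (per-pixel mean over the cell mask — means rather
than sums so the features are size-independent; a sum option exists),
lipid/protein ratio (of the means; protein 0 flags the record and
drops it from selection), lipid and protein intensity over the
cytoplasm mask, LD area (px²), LD number, LD area fraction, and lipid
intensity over the LD mask (0 with a flag when a cell has no LDs).

## Feature selection

Features separating PM-positive from PM-negative specimens are found
by the pooled two-sample Student t-test: all PM+ cells versus all PM−
cells per feature,

    t = (x̄₁ − x̄₂) / √(s²(1/n₁ + 1/n₂)),

with the pooled variance s² on n₁+n₂−2 degrees of freedom and
two-sided p-values; p < α = 0.05 selects, with no multiple-testing
correction (deliberately matching the procedure this pipeline
reproduces; at cytology sample sizes the t-test is extremely
powerful, so "significant" should be read as "non-null", not "large").
Pooling cells across patients treats cells as exchangeable — correct
under the generator's null, anticonservative in the presence of
patient-level random effects; a per-patient-mean variant is available
behind a flag. Constant features are excluded with a warning.

## K-PCA: the clustered latent feature matrix

The selected features of all training cells are centered (not scaled)
and reduced by full-SVD PCA; the kept component count m is the
smallest explaining ≥ 90% of variance, floored at 2. Because the
features are unscaled, large-variance features (areas, in px²)
dominate PC1 — that is intentional: latent units remain interpretable
in detector/pixel terms. Component signs are fixed by making each
loading vector's largest-magnitude entry positive.

K-means (k = 3, 10 restarts, tolerance 1e-4 on center shift, max 300
iterations, seeded) clusters the latent coordinates, pooled over all
training patients so cluster identities and PC values are comparable
across patients. k = 3 reflects the expected mixture of exfoliated
populations (epithelial, mesothelial, tumor-like) and is configurable.

Reported **Cluster 1** is the *marker cluster*: the raw cluster with
the greatest within-cluster PC1 interquartile range. This
operationalizes the observation that the diagnostically informative
cell population is the one whose latent features diverge most;
PC1-variance and distance-to-centroid ranking strategies are provided
as alternatives. Remaining clusters are ordered by descending size,
ties broken by descending centroid PC1.

Each patient is summarized by the **feature matrix**: per reported
cluster, the median of each kept PC over the patient's cells in that
cluster, plus the cluster's cell count. An empty cluster contributes
count 0 and zero-imputed medians with an audit flag — imputation keeps
the classifier input dense.

## Diagnosis

Patient vectors (k·m medians + k counts, counts raw by default with a
per-patient normalized option) are z-scored with training statistics
(constant entries dropped) and classified by logistic regression
(default), a linear SVM (C = 1) with sigmoid/Platt calibration fitted
on the training decision values, or LDA. Evaluation is leave-one-out
cross-validation at the patient level, refitting *everything* —
selection, PCA, K-means, marker ranking, standardization, classifier —
on each fold's training patients only; this is the leakage-safe
protocol and is verified by an instrumentation test (perturbing the
held-out patient's cells leaves the fold's fitted transform
bit-identical). A "frozen transform" mode reproduces the laxer
fit-once protocol for comparison. Pooled LOOCV probabilities give the
ROC (trapezoid AUC) and the operating cutoff maximizing Youden's J
(ties toward the lower cutoff), from which sensitivity, specificity,
accuracy, NPV and PPV follow.

If a fold selects fewer than two features (typical under the null),
the fold falls back to the full candidate set so every patient is
still scored; this keeps null AUCs defined without inventing signal.

Interpretation: matrix-feature importances are the signed classifier
coefficients on standardized inputs (linear family only); raw-feature
contributions to each PC are the unit-norm PCA loading rows. An
ablation utility reruns LOOCV on morphology-only, composition-only
and combined feature sets.

A supervised cell-level route (ML-PCA) is also provided: the same
centered PCA followed by an SVM or LDA on PC coordinates against
cell-level tumor/normal labels, with patient matrices built from
predicted-tumor-cell statistics.

## The synthetic cohort generator

No clinical images are distributed, so every downstream stage is
exercised on synthetic cohorts with exact ground truth. The generator
emulates lavage smears as three phenotypes of elliptical cells:

| phenotype   | area (px², log-normal) | C_L  | C_P  | LDs (Poisson) | waviness |
|-------------|------------------------|------|------|---------------|----------|
| epithelial  | LN(log 1100, 0.16)     | 0.45 | 1.10 | 1.5           | 0.04     |
| mesothelial | LN(log 2000, 0.16)     | 0.55 | 1.25 | 2.0           | 0.04     |
| marker      | LN(log 4500, 0.20)     | 0.95 | 1.60 | 6.0           | 0.12     |

Cells have a concentric nucleus (25–40% of cell area; DNA channel 3×
the cytoplasmic DNA level), Gaussian-profile lipid droplets (radius
2.2–3.4 px, amplitude 5 detector units) placed in the cytoplasm, a
log-normal per-cell intensity jitter (CV 0.12), and a sinusoidally
perturbed boundary whose amplitude ("waviness") lowers solidity and
roundness and raises perimeter for the marker phenotype. The marker
is also more elongated (axis ratio 0.55–0.88 versus 0.65–0.95). With
these defaults the marker phenotype differs from the normal pool in
the 12 features the selection step is expected to recover (7
morphology: area, major and minor axis, perimeter, solidity,
cytoplasm area, roundness; 5 composition: protein intensity,
lipid/protein ratio, cytoplasmic lipid and protein intensity, LD
number); circularity, eccentricity and whole-cell lipid intensity
co-vary as side effects and may also reach significance at cohort
sample sizes.

Channel formation inverts the unmixing: planted concentrations are
pushed through the inverse calibration matrix to detector signals, so
unmixing a noise-free frame returns the planted chemistry to machine
precision. Additive i.i.d. Gaussian channel noise (sd 0.02) is the
only noise model. Cells are placed largest-first without overlap
(2 px moat); an overfull frame raises an explicit capacity error.

Cohort structure: by default 10 PM-positive and 16 PM-negative
patients, 42 frames/patient, Poisson(12) cells per frame (≈ 500
cells/patient, the per-patient workload the pipeline targets). The
marker fraction is 15% in PM+ and 2% in PM− patients. In PM+ patients
each marker cell additionally receives an *upward half-normal
excursion* in log space — scale (s−1)·σ on area and (s−1)·CV on
channel levels, default s = 2.5 — modelling tumor pleomorphism. The
excursion widens the within-patient dispersion of the marker
population (the divergence signal the marker-cluster ranking keys on)
and vanishes at s = 1; it is upward-skewed rather than symmetric
because symmetric log-widening makes implausibly *small* tumor cells
leak into the normal clusters, destroying marker-cluster capture at
exactly the divergence levels where the PC1 signal appears.
Randomness derives from one seed, split into independent per-patient
substreams so any patient subset is reproducible in isolation.
A deliberately signal-free cohort (for null calibration) must be
requested explicitly (`allow_null=True`).

What the generator does *not* emulate — and hence what green tests do
not establish about clinical data: optical blur and detector shot
noise, debris/mucus background, touching and overlapping cell clumps,
staining-free intensity drift between patients (no patient-level
random effects, which keeps the pooled t-test exactly calibrated
under the null), red-blood-cell contamination, and any real
relationship between chemistry and pathology. Passing tests show the
*algorithms* recover planted structure of the assumed form, not that
the assay works clinically.

## Problem sizes used by the test suite

The study-condition cohort used by the recovery tests is the
generator default above (26 patients, ~13 000 cells) at one fixed
seed; null calibration uses a 16-patient signal-free cohort with 20
label permutations and eight 8-patient cohorts for the
false-selection rate; segmentation quality is pooled over 8 default
frames. These sizes were chosen as the smallest at which the cohort-
level statistics are stable.

## Known limitations

* Absolute latent values (e.g. Cluster1-PC1 medians, thresholds
  derived from them) depend on detector calibration, feature scaling
  and the perimeter estimator; they are not transferable across
  instruments or datasets without recalibration.
* The marker-cluster rule assumes the divergent population is a
  *within*-cluster dispersion outlier in PC1; a tumor population that
  is compact but displaced would be better served by the
  `centroid_distance` strategy.
* With k = 3 fixed, cohorts whose normal compartment has more than
  two modes will split it and may dilute the marker cluster.
* LD counting by a global percentile threshold merges droplets closer
  than the threshold contour and undercounts when LD pixel fraction
  exceeds (100 − p)%.
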