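# Methods

`rgpipe` re-implements, as a tested library, a radiogenomic analysis that
predicts the molecular subtype of WHO grade II/III (lower-grade) glioma —
defined by IDH1/2 mutation and TERT-promoter (pTERT) mutation status — from
multi-sequence preoperative MR images. Three kinds of information are
compared under an identical evaluation protocol: patient age, handcrafted
radiomic features of the lesion, and texture features read out of a
convolutional network, classified by a linear support vector machine under
patient-grouped 10-fold nested cross-validation.

## Cohort model (synthetic data)

Real imaging cohorts of this kind are not redistributable, so the package
ships a generator (`rgpipe.synthetic`) whose defaults define the study
conditions used throughout the tests and the acceptance script.

Each patient has four pre-aligned sequences (T1W, T2W, GdT1W, FLAIR) on a
64×64×40 grid at 2 mm isotropic spacing (small enough for desk-scale runs),
an ellipsoidal lesion VOI with per-axis radii drawn from 8–16 mm, and a
mirrored contralateral "normal tissue" VOI obtained by flipping the lesion
mask across the sagittal midline. Lesion centers are drawn across the full
width of the brain, so a fraction of lesions cross the midline; their mirror
overlaps the lesion and those patients are flagged
`excluded_from_normal_analysis` (at default settings roughly a quarter to a
third of patients, comparable to the 37/164 exclusions seen in a real
164-patient cohort of this design).

The lesion interior is a Gaussian random field: white noise smoothed with an
isotropic Gaussian kernel, rescaled to a target SD (contrast, base 8
intensity units), on top of a sequence-specific mean shift (T2W/FLAIR
hyperintense, T1W hypointense, GdT1W mildly enhancing). Genotype enters
through three scalars, all proportional to `texture_effect` with per-class
direction +1 / 0 / −1 (IDHwt / co-mutated / pTERT-wild-type): the lesion
mean (±2 units per unit effect), the contrast and the correlation length
(±12% per unit effect). Age is Gaussian (base mean 46 y, SD 11, clipped to
20–85) with a per-class shift of ±`age_effect` years, IDH wild type oldest —
the direction seen clinically. Scanner field strength (1.5 T with
probability 0.55) is independent of genotype by default so the cohort
homogeneity chi-squared test is null; a config knob can induce association
for testing. Defaults `texture_effect=1`, `age_effect=5` give a plausible,
non-trivial signal; the "strong" condition used for parameter-recovery runs
is `texture_effect=3`.

Setting both effects to zero produces an exact null cohort (genotype
independent of every covariate). The generator is bitwise deterministic
under its seed: a global seed fans out to per-patient and per-stage seeds
via a CRC-based derivation (`core.child_seed`).

What the generator does *not* emulate: MR physics, bias fields, motion,
multi-site intensity differences, anatomically realistic lesion shapes or
locations, or any estimate of the true effect sizes separating real
genotypes. Passing tests therefore demonstrate that the pipeline mechanics
(normalization, feature extraction, leakage-free model selection, scoring,
statistics) are correct and that genuine class signal is recovered when
present — not that any particular accuracy is attainable on real patients.

## Preprocessing

Two normalization dialects serve the radiomic branch: for T1W, GdT1W and
FLAIR, voxels in the top 0.1% of the intensity histogram are treated as
high-signal noise and the remaining 99.9% of the range is reallocated
linearly to 256 gray levels; for T2W, 100% of the range is reallocated.
Flagged noise voxels are pinned to the top level rather than removed, so the
grid stays dense for downstream operations. Quantization uses the fixed-bin
rule `level = floor((v − min)·n/(max − min))` capped at `n−1`; a constant
volume maps to level 0 by convention, without error. The CNN branch instead
rescales each volume so its 2.5th/97.5th percentiles (computed per volume,
over all slices) map to 0/1, clipping outside.

Derived channels: `T2Edge` is the per-axial-slice 2D Prewitt gradient
magnitude of the normalized T2W volume (replicate padding at borders; slices
independent), and `Gdzscore` is a voxelwise contrast-enhancement measure,
implemented as the brain-masked z-score of the GdT1W − T1W difference. The
exact enhancement formula used historically is not public, so the z-score is
the package's definition and is exposed as a strategy hook. Both derived
channels are re-quantized (full range, 256 levels) before histogram features
so entropy and uniformity see discrete levels.

The lesion image for the CNN branch is cut on the center axial slice of the
VOI (middle of the occupied slice range, ties broken to the lower index), as
the tight 2D bounding box of the VOI on that slice, and resized to 243×243
by bilinear interpolation regardless of aspect ratio. Registration is an
identity hook: synthetic cohorts are generated aligned, and real data are
expected pre-registered.

## Radiomic features

The default registry yields 64 values: 9 first-order statistics (mean,
population SD, skewness, Pearson kurtosis, median, 10th/90th percentiles,
Shannon entropy and uniformity of the 256-bin histogram) on each of 6
channels (four sequences + T2Edge + Gdzscore) = 54; 7 shape descriptors
(volume in mL, mesh surface area, sphericity `π^{1/3}(6V)^{2/3}/A`, maximum
3D diameter, elongation and flatness from the principal-axis eigenvalues,
surface-to-volume ratio); and the 3 world-coordinate components of the VOI
weight center. The authentic historical feature list is not public; the
registry is declarative so it can be substituted. Surface area uses marching
cubes on a lightly smoothed mask (σ = 0.5 voxel) because a raw binary
isosurface overestimates curved areas by a staircase factor (a digitized
10 mm sphere then reads sphericity ≈ 0.97 instead of ≈ 0.92); masks too
small to smooth fall back to the binary surface. Degenerate regions
(constant, or under two voxels) report 0 for spread statistics with a
warning rather than NaN.

## Convolutional texture features

Each 243×243 lesion image is augmented into 72 views: nine 227×227 crops at
shifts of 0/±8 px about the center, four right-angle rotations, horizontal
flip or not — in that order of application. All views are used for SVM
training; scoring uses only the center view (no shift/rotation/flip), so
augmentation never leaks into evaluation.

The extractor is a contract: any deterministic network exposing flattened
per-layer activations (ReLU/dropout excluded) can back it. The shipped
backend is a fixed-seed random-weight convolutional stack with an
AlexNet-like topology (conv1–conv5 with pooling, fc6–fc8; He-initialized
weights from a seeded generator; pre-activation outputs exposed). Random
convolutional projections preserve enough texture structure to drive layer
selection and classification mechanics, and make every analysis runnable
with no downloads; the extractor seed is part of experiment provenance. Per
layer, 1000 neurons (or the whole layer if smaller) are sampled once per
analysis and reused for every patient and split; the four sequences'
subsampled vectors are concatenated in fixed order T1W‖T2W‖GdT1W‖FLAIR,
giving 4000 features at the default.

Layer selection runs the lesion-vs-normal classification (patients with a
valid mirrored VOI only; each contributes one lesion and one normal sample,
kept in the same fold) per exposed layer and picks the layer with the
highest mean balanced accuracy, reporting per-layer accuracy ± 95% CI.

## Classification protocol

All cross-validation is grouped at the patient level, outer and inner: the
augmented views of one patient never straddle any train/test boundary.
Outer folds (default k=10) are stratified on the task label, falling back to
unstratified with a warning when a class has fewer members than folds. Per
outer fold, fit on training patients only: feature standardization
(z-score; configurable), one-way-ANOVA F screening to the top `m_select`
features (default 4000; ties broken by feature index; flat features get
F=0), and an inner CV (default k=5) choosing the linear-SVM cost from a
log-spaced grid 10⁻³…10³ by balanced accuracy on center views (ties to the
smaller cost). The final SVM trains on every augmented training row and is
scored on the test patients' center views: balanced accuracy (mean per-class
recall) and AUPRC in average-precision form from signed distances to the
separating hyperplane, one-vs-rest averaged over the classes present for the
three-class task. The same fold plan is reused across the four feature sets
of a task so fold accuracies are paired.

The chance level is estimated by re-running the full nested CV on the age
feature with genotype labels permuted at the patient level (fresh stratified
folds per permutation; one permutation by default, configurable).

## Statistics

Per task: a one-tailed Welch t-test (Satterthwaite df) of each feature set's
fold accuracies against the chance run's; one-way ANOVA across the four
feature sets with Tukey-Kramer pairwise comparisons via the studentized
range distribution (unequal-n form), the ANOVA p Bonferroni-multiplied by
the number of tasks (3), capped at 1 with the raw product retained; t-based
95% CI half-widths (appropriate at n=10 folds); and a Pearson chi-squared
homogeneity test without continuity correction — the uncorrected form is
what reproduces the printed subtype-by-scanner statistic 3.0367 exactly.
Degenerate conventions: identical zero-variance samples give Welch p=0.5;
all-identical ANOVA groups give F=0.

## Numerical and design choices

* Quantization divisor is the data range (max−min); deleted-voxel pinning,
  per-volume percentiles, bilinear resize, lower-index tie-breaks are all
  stated conventions where the historical analysis is silent.
* Grayscale lesion images are replicated to the extractor's 3 input
  channels.
* Neuron subsampling happens per layer before cross-sequence concatenation,
  and the same indices are reused across analyses of one experiment.
* SVM fits use liblinear with a fixed random state and tolerance 1e-4, so
  identical training data give identical models (the basis of the
  no-leakage tests).
* Problem sizes in the shipped tests and acceptance script are scaled-down
  study analogues chosen as desk-scale defaults: parameter recovery at
  n=90 with `texture_effect=3`, chance calibration at n=60 over 100
  permutations, lesion-vs-normal layer selection at n=18 with 200
  neurons/layer.

## Known limitations

* The random-projection extractor is not a trained network; absolute
  accuracies from it are not comparable to a pretrained backbone, only the
  pipeline mechanics and relative comparisons are meaningful.
* The 61-feature radiomic registry is a faithful reconstruction of the
  printed *count*, not of the exact historical list.
* AUPRC for a fold skips classes without both a positive and a negative
  test sample (stratification makes this rare).
* The Gdzscore definition is this package's own (see above).
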