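# Methods

`thermoga` implements a two-stage evolutionary ensemble for binary
diagnosis from breast thermograms, together with the texture features that
feed it. This note records the model, the defaults and the design choices
a maintainer would want explained.

## Problem setting

A static infrared exam yields one temperature matrix per breast, already
segmented (a binary tissue mask). Tumour vascularization and metabolism
raise local skin temperature, so the diagnostic signal is a localized
thermal asymmetry. The pipeline turns an exam into a fixed-length feature
vector, then searches (1) the SVM hyperparameter grid and (2) the space of
feature subsets with two genetic algorithms (GAs), returning a final
classifier and the smallest best-performing column subset.

## Feature extraction

Six named groups combine four extractor families. Per exam, the
left-breast fragment is computed first, then the right; order within a
fragment follows the group recipe.

**GLCM.** Masked temperatures are min–max quantized per breast to 256
levels (per-breast scaling removes absolute temperature offsets between
patients and cameras). Co-occurrence matrices at distance 1 and four
directions (0°, 45°, 90°, 135°, scikit-image offset convention) count only
pixel pairs with both endpoints inside the mask, are symmetrized and
normalized, and yield six descriptors each: contrast, dissimilarity,
homogeneity, energy, correlation, ASM. Correlation of a zero-variance
matrix is defined as 0 (a constant image has no linear structure to
correlate). 6 × 4 × 2 breasts = 48 features.

**LTP spectra.** Local ternary patterns with dead-zone threshold
`t = 0.1 °C` (configurable; the default is a typical thermal-camera
sensitivity, NETD). Each interior masked pixel compares its
8-neighborhood to the center: code +1 above `center + t`, −1 below
`center − t`, else 0; neighbors outside the mask contribute the neutral
code. "Spectrum k" (k = 0..8) is the binary map of pixels with exactly k
positive codes; the nine maps partition the interior. "8 LTP" in group
recipes means spectra 0–7.

**Fractal trio.** Higuchi fractal dimension (curve-length regression,
`k_max = 8`), Petrosian fractal dimension (sign-change closed form) and
the Hurst exponent applied to the row-major flattening of a spectrum map
cropped to the bounding box of interior masked pixels. The Hurst estimate
uses rescaled-range analysis over non-overlapping dyadic windows
(≥ 8 samples) with the Anis–Lloyd/Peters expected-R/S correction: the raw
R/S regression slope overestimates H on short uncorrelated series (≈ 0.56
at length 2048), while the corrected estimator is unbiased (≈ 0.50 ± 0.03
measured over 20 seeded white-noise series). Constant series return
sentinels (Higuchi 1.0, Petrosian 1.0, Hurst 0.5) so feature vectors stay
finite; near-constancy is detected with a 1e-10 relative tolerance because
a wavelet transform of a mathematically constant map carries ~1e-16
jitter.

**Wavelet–fractal.** Each spectrum map (0–7) is decomposed one level with
each Daubechies family db1–db8; the fractal trio of the flattened
approximation band gives 3 × 8 × 8 = 192 values per breast. "8 wavelets"
as eight Daubechies orders is the only reading consistent with the group's
total of 384.

**LTP polarity histograms** (only in the `glcm_8ltp` group). The +1 codes
of a pixel's neighborhood form an 8-bit "upper" byte, the −1 codes a
"lower" byte; each byte distribution is binned into 25 equal-width bins
over [0, 256) and normalized to frequencies: 2 × 25 × 2 breasts = 100
features. This reconstruction matches the group's printed feature count;
the bin width is a package choice.

Group dimensionalities: 384, 48, 48, 60, 18, 148.

## Evaluation protocol

One run-level seed fixes a stratified 70/30 split and a stratified 4-fold
partition of the 70% part. GA fitness is the mean AUC over the four folds
(decision-function scores); final reported metrics (AUC, F1, ACC, SENS,
SPEC, with *cancer* as positive class) come from refitting on the full
70% and scoring the untouched 30% hold-out. Fixing the partitions once
per run makes fitness comparable across individuals and generations.

The classifier is the nu-parameterized SVM (`sklearn.svm.NuSVC`) — the
only formulation in which "nu" is a hyperparameter. Failed fits (nu
infeasible for a fold's class balance, numerically degenerate kernels)
score fitness 0 instead of raising, so evolution discards them. Solver
iterations are capped at 100,000: well-behaved fits at study sizes
converge in under a thousand iterations, while degenerate combinations
(tolerance 1e-8 on an inseparable subset) can otherwise spin for minutes;
a capped non-converged fit either returns usable scores or fails to
fitness 0.

## Stage 1: model selection ("Bucket of Models")

The hyperparameter grid: tolerance (8 decades, 0.1…1e-8), gamma and coef0
(58 values: 8 decades then 0.2…5.1 by 0.1), nu (0.2…0.6), degree (1–3),
kernel (rbf, poly, sigmoid). Not every parameter is relevant to every
kernel (rbf ignores coef0 and degree; only poly uses degree); a
configuration's *canonical form* keeps the relevant values only, and the
exhaustive count of distinct canonical configurations is
2,320 (rbf) + 403,680 (poly) + 134,560 (sigmoid) = 540,560.

Each genome is six indices into the parameter lists. Per generation
(defaults: 140 individuals, 30 generations):

* 10 elitist copies of the ranked best;
* 40 children by balanced uniform crossover (each child takes exactly 3
  genes per parent; parents drawn from the 10 elites with replacement —
  the elite pool is a package choice, keeping selection pressure);
* 20 asexual ±1 index variants of the top-ranked individuals, genes
  visited in fixed order, out-of-bounds neighbors skipped (the lists are
  ordered scales; wrapping would jump regimes);
* 10 single-gene mutants: one from the top three, one from the bottom
  three, eight from anywhere;
* 60 uniformly random genomes.

Every individual of every generation is evaluated — no fitness caching —
so the audited training count is exactly `population × generations`
(4,200 at the defaults). When the best fitness is flat (within 1e-9) for
10 consecutive generations, a *decimation* event keeps only the rank-1
individual and regenerates the other 139 at random. The stage returns the
10 best distinct canonical configurations seen anywhere in the run (not
only the final generation), ties broken by earlier discovery.

## Stage 2: feature selection

Binary genomes over the feature columns, at least `min_active = 1` bit
set. Defaults: 140 individuals, 100 generations, quotas 20 elitist
copies / 40 crossover children / 6 mutants / 74 random genomes. Crossover
is single-cutoff (cutoff uniform in [1, length−1]); children below the
active floor are repaired by activating random bits. Mutation flips
exactly one bit, never violating the floor; with quota 6, one mutant
comes from the top three, one from the bottom three, four from anywhere.
Random genomes activate each bit with probability 1/2.

Fitness in the default `top_model` mode is the CV AUC of the bucket's
rank-1 model restricted to the active columns — one training per
individual, giving the audited 14,000 trainings at the defaults and
18,200 for the two stages together. The optional `model_set_max` mode
scores a subset by the best of all ten bucket models (ten trainings per
individual) for users who want the whole bucket as the oracle. Ranking is
lexicographic: higher AUC, then *fewer* active columns, then earlier
discovery — the parsimony tie-break is what drives the subset toward the
smallest sufficient set once fitness saturates. Decimation fires on the
same flat-best rule, where "improvement" includes shrinking the subset at
equal AUC.

## Percentile baseline

The filter comparison scores each column with the ANOVA-F statistic and
activates the top `ceil(percentile × d)` columns. When compared against a
GA-selected mask, the baseline is taken at the same cardinality and both
masks are scored with the same bucket model under the same protocol.

## Synthetic data

`make_roi_pairs` emulates a balanced static-thermography study (default
80 exams, 64×64 matrices, baseline 33 °C, i.i.d. Gaussian camera noise
0.1 °C). Cancer exams add a 2-D Gaussian hot spot (amplitude 2 °C, radius
8 px, uniformly placed in the central half of one breast) — the localized
contralateral asymmetry the features target. It does **not** model
bioheat diffusion physics, vascular branching patterns, fixed-pattern
camera noise, patient-to-patient anatomy, or segmentation errors, so
passing tests show the pipeline detects controlled asymmetries, not
clinical performance.

`make_feature_table` draws class-conditional unit Gaussians; a known
subset of columns (default 10 of 50) is shifted by `effect_size` (default
1.5) pooled standard deviations in the cancer class. At these defaults
the two classes are strongly separable from the informative columns
alone, which is what lets recovery benchmarks measure *selection*
behavior rather than classifier capacity.

## Problem sizes used in tests and the acceptance script

The budget-audit run uses the full default GA budgets (140 × 30 +
140 × 100 = 18,200 trained models) on a 60 × 18 synthetic table — small
enough that the complete run takes a few minutes single-core. The
recovery benchmark uses the 160 × 50 table with a population of 40,
10 model-selection generations, and the default 100 feature-selection
generations: fitness saturates within a few generations on this strongly
separable table, and the remaining generations exercise the parsimony
tie-break, which prunes roughly one noise column per generation or two;
the stage-2 generation count therefore stays at its default while the
population is reduced for speed.

## Known limitations

* AUC granularity at small validation folds makes ties at 1.0 common;
  subset ranking then depends entirely on the parsimony tie-break, so
  short feature-selection runs under-prune.
* The R/S Hurst estimator, even corrected, has high variance on series
  shorter than ~500 samples; spectrum maps from small ROIs give noisy
  Hurst features.
* The "100 LTP features" construction (25-bin polarity histograms) is one
  of several readings consistent with the group's printed total; the bin
  count is exposed in the recipe.
* Masked-out pixels are excluded from GLCM pairs and neutral in LTP
  codes, but wavelet decomposition sees the rectangular bounding box of
  the interior mask, zeros included; heavily non-convex masks therefore
  leak some background structure into wavelet bands.
* No probability calibration; decision scores are used for AUC only.
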