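# Methods

`rsnpfs` implements a complete preoperative resting-state-connectivity →
progression-free-survival (PFS) analysis for high-grade glioma cohorts, plus
a synthetic cohort generator that makes every stage testable without
patient data. This note documents the models, the defaults and why they
were chosen, the numerical conventions, and what the synthetic experiments
do and do not demonstrate.

## Functional connectivity features

Each subject contributes voxelwise time series inside the ROIs of 15 named
resting-state networks (SMD, SMI, CON, AUD, DMN, PMN, VIS, FPN, SAL, VAN,
DAN, MTL, REW, THA, BGA). Before any correlation, missing or non-finite
samples in a network block are imputed with the *ROI-wise mean* — read here
as the grand mean over all finite entries of that network's
voxels × timepoints block. The phrase is ambiguous (per-voxel and
per-timepoint means are alternatives); the grand mean is the only reading
that stays well defined when a whole timepoint or a whole voxel is missing,
which is why it is the convention here.

Similarity features:

- **Within-network** (15 features): mean of the *strictly* lower triangle of
  the voxel–voxel Pearson correlation matrix. Self-correlations are
  excluded; including the unit diagonal would bias every within-network
  value toward 1 by construction.
- **Between-network** (105 features): mean of the full |A|×|B| matrix of
  voxel-to-voxel Pearson correlations between two networks' time-series
  sets (correlations over time, averaged over all voxel pairs).

Canonical feature order is the row-major upper triangle (including the
diagonal) of the 15×15 network grid, 120 features in total. Voxels with
zero temporal variance (possible after constant imputation) have undefined
correlations; their pairs are excluded from the averages with a warning —
silently scoring them 0 would bias the means.

## MRMR feature selection

For a continuous outcome, relevance of feature *f* is |Pearson r(f, PFS)|
and redundancy against a selected set *S* is the mean |Pearson r(f, s)| over
s ∈ S. Ranking is greedy forward selection with the difference criterion
(relevance − redundancy, the MID scheme); the quotient scheme is available
as an option, and neither is asserted to be the historical original — the
method is usually described only verbally. Ties break toward the lower
feature index so rankings are reproducible. The selection size defaults to
k = 15; a PCA-based cumulative-variance diagnostic is provided to sanity
check a chosen k but never gates selection.

Selection is nested: inside every leave-one-out fold the held-out subject
is removed *before* ranking, and the fold's model sees only that fold's
top-k features.

## The feed-forward regressor

Architecture: input (k = 15 features) → three equally sized fully connected
layers, each followed by a sigmoid activation and layer normalization (zero
mean / unit variance across the layer's units per sample, learnable
per-unit gain and offset), → a single *linear* output in months. The output
layer is linear because PFS spans 0.5–24 months; a bounded activation could
not reach the upper range. Hidden widths come from {5, 10, 15}.

Training minimizes MSE, MAE, or Huber loss (δ configurable, default 1.0)
with L-BFGS (memory 10, gradient tolerance 1e-7, iteration cap 500 —
unstated in most descriptions of such pipelines; these are standard
small-problem values and all configurable). Gradients are exact,
hand-derived backpropagation through the sigmoid/layer-norm stack; a unit
test checks them against finite differences. Weights initialize from a
seeded symmetric uniform distribution scaled by 1/√fan-in; gains start at
1, biases and offsets at 0. Every stochastic step is seeded, so a full run
is a pure function of (data, config, seed).

### Early stopping and model selection

During one training run, a validation loss is evaluated at every L-BFGS
iterate; training stops after 20 consecutive non-improving checks (or on
gradient tolerance / the iteration cap) and the parameters of the best
validation checkpoint are returned.

The hyperparameter search enumerates widths × loss kinds and repeats each
configuration from ~50 fresh initializations (reduced in the scaled-down
experiments), each on freshly drawn augmented data. Because every restart
draws its *own* validation subjects, raw validation losses are not
comparable across restarts — a restart whose validation subjects happen to
have low outcome variance would win regardless of quality. The search
therefore selects by a **skill score**: validation loss divided by the loss
of the best constant predictor (mean; median for MAE) on the same
validation set. A score of 1 means no better than a trivial predictor.
This is the package's convention for "best model"; raw validation loss
remains the early-stopping criterion inside a single run.

## Augmentation and the validation split

Augmented training samples are built at the FC level: per sample, draw a
timepoint fraction and a voxel fraction uniformly from 70–80%, subsample
without replacement, and recompute the full 120-feature vector on the
subsample. Augmented samples inherit their source subject's (clipped)
outcome unchanged — augmentation perturbs inputs only. Subsampled
correlation averages are nearly unbiased: at 4000-frame runs the mean of
500 augmented vectors sits within ±0.05 of the full-data vector on every
feature (tested).

Per optimization cycle, the number of augmented samples is drawn from
10–500 and a 5–20% validation subset is reserved. Two conventions here
matter and are this package's own choices:

- **Source coverage.** Sources cycle through the fold's training subjects in
  a random order rather than being drawn i.i.d., so small augmented sets
  still cover most subjects.
- **Subject-grouped validation.** The validation fraction is applied to
  *subjects*, not rows: a random 5–20% of the fold's training subjects
  contribute only validation rows. Row-wise splitting would put jittered
  copies of every training subject into the validation set, so validation
  loss would measure reconstruction of already-seen subjects and could not
  detect overfitting to outcome noise. Grouping makes it an estimate of
  cross-subject generalization, which is what early stopping and model
  selection need. The validation split is redrawn every optimization cycle.

The held-out LOOCV subject contributes nothing to selection, augmentation,
or validation in its fold; leakage tests assert that relabeling the
held-out subject changes neither the fold's selected features nor its
prediction.

## Outcomes, metrics, survival analysis

PFS outliers are clipped at 24 months before modeling. Headline metrics:
RMSE, MAE, and R² as the coefficient of determination 1 − SS_res/SS_tot
(the stricter choice; squared correlation is easy to recompute from the
stored predictions), with a two-sided p-value from the test of zero
correlation between actual and predicted values. A linear least-squares
baseline shares the identical fold structure and per-fold selected
features, with no augmentation.

Progression classification follows the RANO 2.0 conventions for high-grade
glioma: measurable lesions are contrast-enhancing, visible on ≥2 axial
slices, with *both* perpendicular diameters strictly >10 mm (the stricter
of the two possible readings of "perpendicular measurements greater than
10 mm"); progression is a ≥25% increase in the summed perpendicular
diameter products, or a significant non-enhancing FLAIR/T2 increase,
which is accepted as a boolean flag rather than modeled. PFS in months uses
a 30.44-day month (mean Gregorian month; the convention is otherwise
arbitrary).

Kaplan–Meier curves, the two-group log-rank test and the univariate Cox
proportional-hazards fit are delegated to `lifelines`. lifelines handles
tied event times with Efron's correction; the survival times this package
produces are continuous (ties have measure zero), where Efron and Breslow
partial likelihoods coincide — the test suite checks the fitted coefficient
against an independently written Breslow score equation. Predicted-PFS
stratification splits at the median with ties assigned to the low group,
so an odd cohort of 45 splits 23 low / 22 high.

## Spatial map analyses

Tumor frequency maps are voxelwise means of binary segmentations. The
voxelwise PFS association is the point-biserial (Pearson) correlation
between tumor presence and PFS across subjects, computed only at voxels
with ≥2 tumor and ≥2 non-tumor subjects; undefined voxels carry NaN as the
sentinel (NaN survives float NIfTI round-trips). Cliff's delta between
control and patient probability maps is computed per network over that
network's own support voxels — off-network voxels are mostly background in
both groups and would dilute the contrast toward zero. Magnitude labels
use |d| < 0.33 negligible/small, 0.33–0.47 moderate, ≥ 0.47 large.
Per-network feature weights average the MRMR importance scores of the 15
pairs involving each network (the within pair plus 14 between pairs);
"feature weights" could alternatively mean trained-model weights, but the
selection scores are deterministic, fold-stable and tied to the selection
stage that defines them. Weight maps are the voxelwise dot product of the
15 network weights with the network probability maps.

## The synthetic cohort generator

The generator emulates the statistical structure of a 45-patient
preoperative glioblastoma resting-state cohort; no public accession exists
for such data, so it is the package's test bed and the input to the
acceptance experiments.

- **Parcellation**: seeded region growth on a 24³ grid; 15 disjoint,
  spatially clustered ROIs of 12 voxels each by default. Clusters look like
  compact ROIs without requiring an anatomical template.
- **Time series**: latent-signal model — voxel v in network g is
  √ρ_g·L_g(t) + √(1−ρ_g)·σ·ε_v(t) with unit-variance latents L drawn with
  a per-subject cross-network correlation matrix. At σ = 1 the expected
  within-network similarity is exactly ρ_g and the between-network
  similarity is √(ρ_i ρ_j)·corr(L_i, L_j), giving analytic oracles for the
  FC extractor. Runs default to 300 frames — a typical resting-state
  acquisition length.
- **Between-subject structure**: cross-subject FC variation in real
  resting-state cohorts is dominated by a few population-wide connectivity
  modes, so the generator draws each subject's latent correlation matrix
  from *fixed population factor loadings* (a structural constant of the
  generator) with per-subject mode strengths (SD 0.25) plus small
  idiosyncratic loading noise (SD 0.20), and per-subject ρ_g ~ U(0.3, 0.7).
  The low-rank-plus-noise structure matters: if every subject instead drew
  an independent random correlation matrix, the 115 inactive features would
  act as independent spurious correlates at n = 45 and no smooth learner
  could recover the planted signal.
- **Outcomes**: PFS = floor + base + scale·softplus(u − t)², a smooth
  threshold-saturation ("knee") response in the standardized weighted sum u
  of five planted FC features (defaults: SMD×VAN, SMI×VIS, DMN×VAN,
  PMN×THA, MTL×THA — cross-network pairs linking somatomotor, attention,
  default-mode and thalamic systems): PFS is flat near the floor below the
  threshold and rises steeply above it. The parameters are calibrated so
  the simulated cohort reproduces the target cohort's PFS distribution
  (median ≈ 7, SD ≈ 5.5 months, right-skewed, rare long survivors near the
  24-month clip) *and* its qualitative model comparison — a linear model on
  the same features degrades markedly while remaining monotone enough for
  correlation-based MRMR to detect the active features. A sigmoid and an
  identity link are available as options. With `noise_sd=None` the noise SD
  is set to SD(signal)/3, a 9:1 signal-to-noise variance ratio (generative
  R² = 0.9). OS is PFS plus an exponential excess (mean 8 months), so
  OS ≥ PFS always; PFS is floored at 0.5 months.
- **Probability maps**: control maps carry high probabilities (0.82–0.98)
  on each network's support over a low background; patient maps are
  attenuated copies plus noise, clipped to [0, 1].
- **Segmentations**: connected region-grown clusters; overlap with
  designated "short-PFS" networks (DAN, VIS, FPN, DMN by default) adds a
  proportional negative PFS shift.

What the generator does *not* emulate: hemodynamics, spatial autocorrelation
of BOLD noise, realistic anatomy or lesion-induced signal dropout, scanner
artifacts, or clinical covariates. Passing tests therefore demonstrate that
the pipeline recovers planted, recoverable structure under the stated noise
model — not that the method would attain the same accuracy on real imaging.

## Scaled-down experiment sizes

The acceptance experiments run the full nested pipeline at the cohort's
native size (45 subjects, 120 features, 5 active) but with a reduced search
grid — hidden widths {5, 10}, Huber loss (δ = 1, robust to the planted
outcome noise), 5 restarts per configuration per
fold — and 20 seeded repetitions for the feature-recovery rate. These sizes
keep the whole analysis in the minutes range on one CPU while leaving every
structural element of the method (nesting, augmentation, restarts, search)
in place.

## Known limitations

- The ANN's LOOCV accuracy on the synthetic cohort (R² ≈ 0.5–0.6 across
  cohort seeds) sits well below the generative ceiling (0.9): with 44
  training subjects the network still absorbs some outcome noise and
  occasionally misses the rare long survivors, which keeps the
  squared-error metrics close to the linear baseline's even though the ANN
  is clearly better on absolute error.
- Model selection by skill score assumes the trivial-predictor loss is a
  fair difficulty normalizer for small validation sets; with ≤3 validation
  subjects it remains noisy.
- `classify_progression` treats the FLAIR/T2 judgement as an input flag;
  no pseudoprogression adjudication or steroid-dose modeling.
- The Cox wrapper is univariate (single binary group) by design.
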