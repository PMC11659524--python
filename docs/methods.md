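# Methods

This note records the modeling choices, defaults, and limitations of the
package, module by module.

## Signature scoring

A TME signature score is the arithmetic mean of the normalized expression of
the signature's member genes. Normalization is `log2(TPM + 1)` followed by a
per-gene z-score across the cohort (sample standard deviation, ddof = 1);
genes constant across the cohort map to all-zero rows rather than NaN. The
"average normalized expression" construction admits variants (ssGSEA/GSVA
scoring, median aggregation); the mean-of-z reading is the simplest and is
the one implemented — the normalization is deliberately confined to
`normalize_expression` so a different scheme can be swapped in.

The bundled registry (`histotme/data/tme_signatures_default.gmt`) carries 30
signatures in four functional groups — 11 antitumor immune, 11 protumor
immune, 5 angiogenesis/stroma, 3 malignant properties — with small
illustrative marker-gene sets (5–8 genes each). **These gene memberships are
defaults for running and testing the pipeline, not curated references**;
users with published gene-set definitions should supply their own GMT
(group labels ride in the GMT description field as `group=<label>`).
Missing-gene policy: genes absent from the expression matrix are dropped
with a logged warning and a recorded coverage fraction; below 50% coverage
the signature errors, because the mean over a sliver of a gene set no longer
measures what the signature names.

## Slide preprocessing

* Tissue mask: Otsu threshold on the median-blurred (7×7) saturation channel
  of the HSV transform, computed on a downsampled thumbnail (default 32×).
  This separates tissue from glass background; it cannot distinguish tumor
  from benign tissue, and is documented as tissue masking.
* Tiles: non-overlapping grid from the slide origin, physical side 256 µm,
  `tile_px = round(tile_um / mpp)` (512 px at 0.5 µm/px). A tile is kept iff
  its tissue fraction strictly exceeds 0.25. Coordinates are 0-based
  top-left corners in the level-0 pixel frame, half-open boxes.
* Macenko normalization: optical density `OD = −log10((I+1)/256)`; pixels
  with all channels below the OD floor 0.15 are treated as unstained; the
  stain plane is the span of the two leading eigenvectors of the OD
  covariance; stain vectors sit at the (1, 99) angular percentiles.
  Hematoxylin is ordered first by its larger red-channel OD (hematoxylin
  absorbs red more strongly than eosin). Robust concentration maxima are
  99th percentiles. Tiles with under 1% stained pixels or a rank-deficient
  OD cloud raise `NotEnoughStainError` and are embedded unnormalized (and
  logged) rather than dropped — dropping would bias bags against sparsely
  stained regions.
* Per-tile standardization to zero mean/unit variance is computed jointly
  over pixels and channels; constant tiles map to zeros with a warning.
* Patients with several slides get their tiles pooled into one bag, matching
  the patient-level supervision.
* The bundled `SyntheticEmbedder` (a frozen random projection of tile
  summary statistics) exists so the pipeline is runnable and testable; it
  carries no histologic knowledge. Foundation-model encoders plug in behind
  the same contract (batch of standardized tiles → finite fixed-dim rows).

## AB-MIL regression

Gated attention (tanh/sigmoid two-branch, per the AB-MIL formulation) with a
single hidden layer per output head (ReLU). Defaults follow the training
recipe the pipeline was designed around: Huber δ = 1, AdamW lr 1e-4, weight
decay 1e-4 (biases excluded from decay), batch size 1 with gradient
accumulation over 8 bags, at most 40 epochs, early stopping after 10 epochs
without validation improvement, model restored to the best validation
epoch. Early stopping monitors the mean per-signature validation Huber loss
of the whole model. When no validation set is passed, a seeded 10% split of
training patients is held out. Targets are z-scored per signature on the
training cohort and de-scaled at prediction. Attention hidden width
defaults to 384 (sized for 768–2048-dim foundation-model embeddings);
`mlp_hidden_dim` defaults to 256.

The implementation is pure NumPy — forward, backward, and AdamW are
hand-written — and fully deterministic under a fixed seed, which the test
suite asserts bit-for-bit. Predictions are exactly invariant to tile order
and to duplicating every tile (softmax weights halve, the weighted sum is
unchanged).

**Benchmark configuration.** The planted-bag benchmark (64-dim synthetic
embeddings, 200 training / 50 held-out patients) uses a 128-unit attention
module, 64-unit heads, and lr 1e-3. The narrower widths match the 64-dim
inputs. The higher learning rate is a property of the synthetic scale: with
lr 1e-4 the optimizer moves too little in 200 × 40 bag updates to fit the
planted linear signal (validation Huber stays near its initial value and
held-out mean r ≈ 0.3), while lr 1e-3 reaches mean held-out Pearson ≈ 0.87.
On real cohorts (an order of magnitude more bags and epochs' worth of
updates, different target variance) the recipe defaults stand.

## Synthetic data

`gen_bags` plants, per patient, a standard-normal 30-vector `s`; a fraction
(default 0.2) of the patient's tiles (50–200 per bag) get their mean shifted
by `Σ_j s_j · u_j` along random orthonormal directions `u_j`; all tiles have
isotropic Gaussian noise (sd 1). This is the simplest structure under which
attention should up-weight signal tiles. A closed-form ridge regression on
bag means already recovers the signal (held-out r ≥ 0.6 per signature, a
tested property), so MIL performance above that margin is attributable to
the attention mechanism. What the generator does **not** model: spatial
autocorrelation of tiles, batch/stain effects across patients, non-linear
signature-to-morphology maps, or class imbalance — passing tests show the
estimator recovers planted linear structure, not that it matches real-cohort
accuracy.

`gen_cohort` draws 30-dim profiles from a Gaussian mixture (two subtypes by
default, centers `separation` within-cluster sds apart along the
antitumor-immune axis), responder labels from a logistic model on one
planted pairwise interaction feature (default `Coactivation_molecules +
Th2_signature`), and exponential survival times with a 2:1 hazard ratio of
non-responders to responders, censored uniformly. `gen_slide_image` renders
elliptical tissue blobs through a Beer–Lambert two-stain model with smooth
random concentration fields (relative spread 0.6, floor 0.08 — wide enough
that the angular percentiles of the OD cloud reach near-pure-stain pixels,
while pale tissue still clears the Otsu threshold) and returns the analytic
mask, so segmentation and stain estimation are tested against ground truth.

All generators are pure functions of their spec; identical specs give
bit-identical outputs.

## Subtyping

Profiles are scaled per signature by cohort mean/sd; at deployment each
cohort is scaled by its own statistics by default (configurable to reuse the
training statistics), mitigating cross-cohort distribution shift. K is
selected by clustering 80% subsamples (100 bootstrap replicates) at each K
in 2..6 and maximizing the median average-silhouette (Euclidean); clustering
defaults to k-means (k-means++, 10 restarts) with classic PAM (BUILD+SWAP on
Euclidean distances) available via `method="pam"`. Degenerate replicates
whose clustering collapses to one label score −1 so they can never win.
Label switching is resolved deterministically: the cluster with the higher
mean over antitumor-immune signatures is always "Immune-Inflamed". The
subtype classifier is a 500-tree random forest (sqrt features per split)
with out-of-bag accuracy logged and impurity importances (summing to 1)
exposed. PAM assigns by nearest single medoid and is noisier than a
centroid in 30 dimensions; PAM/k-means agreement is only asserted for
well-separated clusters.

## Response prediction

Interaction features for each unordered pair (A, B), A before B in registry
order: `A+B`, `A−B`, `exp(A)·exp(B)`, `exp(A)/exp(B)` (exponentiation keeps
product/quotient features positive and monotone in the signatures, which can
be negative). Profiles with |value| > 50 are rejected to guard `exp`
overflow. Note the exp-product equals `exp(A+B)` and the exp-quotient
`exp(A−B)`: for tree models, which only use split order, the 1740 features
span an 870-dimensional effective split space; the full grammar is kept for
interpretability of selected names. Direction of the asymmetric ops is fixed
to registry order; tree ensembles are insensitive to a global sign flip.

The stratified 70/30 split floors each class's proportional train quota and
hands leftover seats to larger strata first (ties by label order); on a
230-patient cohort with 119/111 classes this yields train 84/77 and test
35/34. Feature selection is a 1000-tree random forest importance ranking
(rows canonicalized by sample id so the result is order-invariant; ties
break by canonical feature order). The number of kept features is tuned by
stratified 5-fold CV of an XGBoost classifier (logistic objective, lr 0.1,
gamma 0.1, early stopping patience 100 on log-loss with validation AUROC
recorded), **with selection re-run inside every fold** — the permuted-label
test asserts this keeps null test AUROC near chance. Ties in mean CV AUROC
go to the smaller k; the final round count is the rounded mean of the
winning folds' best iterations. The final model refits selection and
boosting on the whole training set. The probability cutpoint maximizes
Youden's J over observed probabilities (rule `p ≥ t`, ties to the lowest
threshold) on training predictions, avoiding test-set leakage into the
operating point. SHAP attributions come from XGBoost's exact TreeSHAP
(`pred_contribs`), additive on the margin scale; tests verify additivity
and, on stump ensembles, agreement with brute-force Shapley enumeration.

## Evaluation statistics

AUROC is the Mann–Whitney concordance with ties counted ½ (tested against
pairwise enumeration). DeLong placement-value variance gives normal
approximation CIs (clipped to [0, 1]; degenerate at perfect separation,
with a warning) and the two-sided paired test for comparing two markers on
the same patients; the variance is validated against a 10⁴-replicate
bootstrap. Proportion CIs are exact Clopper–Pearson Beta quantiles.
Survival: two-group log-rank, and univariate Cox PH via lifelines (Efron
tie handling, the R default, matching analyses performed in R). Hazard
ratios are always reported for the indexed group (predicted
responder/Inflamed = 1) versus the other, so HR < 1 means better survival
for that group. All tests are two-sided.

## Problem sizes

The shipped benchmarks run at desk scale: 250 patients × 50–200 tiles ×
64 dims for MIL recovery; 300 samples for K selection (100 bootstrap
replicates, 20 seeds); 400 samples for the response pipeline (20 permuted
seeds, 10 planted-effect seeds). These sizes are where the planted effects
are comfortably identifiable by the closed-form oracles; scaling beyond
them changes runtime, not the logic.

## Known limitations

* The default gene sets are illustrative; scientific use requires curated
  signature definitions.
* SVS support extends only as far as tifffile can read; vendor-specific
  pyramids and metadata mpp extraction are not implemented (pass `--mpp`).
* The synthetic embedder is not a histology encoder; absolute performance
  numbers on synthetic data say nothing about real-slide accuracy.
* Single-machine CPU training only; no GPU path.
* Probability calibration of the response model is out of scope; the Youden
  cutpoint is a ranking-derived operating point, not a calibrated risk
  threshold.
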