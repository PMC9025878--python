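# Methods

## The model

omifuse addresses three-class cancer-subtype calling (LUAD vs. control vs.
LUSC) from heterogeneous sources — RNA-Seq, miRNA-Seq, per-gene copy-number
values, CpG methylation beta values, and whole-slide histology — by **late
fusion**: one probabilistic classifier per modality, combined at the
probability level.

For a sample *x* with per-modality class probabilities *P_j(c_i)* the fused
score of class *c_i* is the weighted sum

    P_fusion(c_i) = Σ_j  w_{i,j} · P_j(c_i)

with a weight matrix *w* of shape (classes × modalities).  Each row of *w*
is constrained to the probability simplex through a row-wise softmax of
unconstrained raw parameters.  The raw parameters are trained by minibatch
Adam on the cross-entropy of the fused true-class score,
`-mean log(max(P_fusion(y), 1e-12))`.  Fused scores are deliberately **not**
renormalized across classes before the argmax or the loss: each score is
already a convex combination of probabilities, and renormalizing would
change nothing about the argmax while hiding the missing-data semantics.

A missing modality is encoded as an exactly all-zero probability row, so it
contributes nothing to the weighted sum; any subset of sources can therefore
be fused for any sample.  A sample with *no* available modality carries no
information and prediction raises an explicit error.

### Softmax placement

The row constraint can be read two ways: softmax inside the forward pass
(gradients flow through it) or a hard projection overwriting the raw
parameters after each optimizer step.  Both are implemented
(`FusionTrainConfig.projection`); the default is the differentiable forward
softmax, because projecting Adam-updated parameters and overwriting them
changes the optimizer-state semantics.  The analytic gradient is verified
against central finite differences for both modes.

### Epoch selection

A stratified validation split (default 10%) monitors fused accuracy each
epoch and the weights of the best-validation epoch are returned.  Ties go to
the **most recent** epoch among equals: validation accuracy is a coarse,
quickly saturating monitor, and among equally accurate epochs the
better-converged weights are preferable.  Set
`FusionTrainConfig.select_best_epoch=False` to keep the final epoch
unconditionally.

### Degenerate cases

* One modality: softmax of a single column is 1, fusion is the identity.
* A modality absent from *all* training samples leaves its weight column
  untouched by data; it is reset to the row mean of the observed columns (a
  neutral weight) with a warning.
* Tied fused scores or tied tile votes resolve to the earlier class in the
  configured order (LUAD, control, LUSC), with a logged warning.

## Per-modality models

**Molecular sources** use an RBF-kernel SVM.  Features are min-max scaled to
[-1, 1] with parameters from the training split only; test values outside
the training range map outside [-1, 1] and are not clipped.  `C` and `gamma`
are chosen from the grid {2⁻⁷, 2⁻⁵, 2⁻², 2, 2⁴, 2⁷} by 5-fold stratified
grid search on training accuracy, then refit with pairwise-coupling
probability estimates.  Constant features scale to 0 with a warning.

**Slides** are cut into non-overlapping square tiles (default 512 px) in
row-major order, dropping partial edge tiles; a tile is background iff the
mean of *all three* RGB channels exceeds 220.  A pluggable tile classifier
predicts a class per tissue tile; slide-level probabilities are tile
fractions (count predicted per class / total tiles) and the slide label is
the majority vote, which equals the argmax of the fractions.  The reference
tile classifier is a multinomial logistic regression on per-tile channel
means — small enough to test the tile-to-slide arithmetic exhaustively; a
convolutional model can be plugged in behind the same fit/predict contract.

## Feature selection

* `drop_missing_features` removes every column with at least one missing
  value (samples untouched).
* `ttest_screen`: pairwise Welch t-tests between the three classes.  The
  Bonferroni family is features × 3 comparisons (the most conservative
  reading).  A feature is kept when it is significant (adjusted p ≤ α,
  default 0.001) in at least `required_comparisons` of the three pairs *and*
  every significant pair also shows |mean difference| ≥ the floor (0.1 for
  copy-number-style data with all three comparisons required; 0.4 for
  beta-value-style data with two of three).  Welch rather than pooled
  variance because class sizes are typically unequal.
* `deg_filter`: max pairwise |log2 fold change| of class means ≥ 2, one-way
  ANOVA p ≤ 0.05 (a single omnibus test is the simplest reading of one
  p-value threshold over three classes), and coefficient of variation over
  all samples ≤ 2.  Requires strictly positive values; the error message
  suggests a pseudocount.
* `mrmr_rank`: greedy mRMR with the MID (difference) criterion — mutual
  information with the label minus mean mutual information with the already
  selected features — after equal-width 3-bin discretization.  Ties break by
  input column order.  How many top-ranked features feed each SVM is a plain
  config value (`PipelineConfig.n_select`, default 10); an inner-CV sweep
  over prefix lengths is possible but not automated.

## Evaluation protocol

Cross-validation is stratified and **patient-wise**: folds are drawn over
patients, so every sample of a patient lands on one side of each split;
per-fold class counts stay within one patient of the even split.  All
data-dependent steps — screening, ranking, scaling, grid search, tile
classifier fitting, fusion-weight training — run inside each training fold.
Metrics are accuracy, weighted F1 (macro also reported), and per-class
one-vs-rest ROC AUC / average precision, macro-averaged; across-fold spread
uses the sample (n−1) standard deviation.

Fusion subsets are evaluated in two regimes: `common` (only samples with
every subset modality present) and `all` (every sample with at least one
subset modality, missing rows zero-filled).  `error_rate_reduction` reports
`100·(wrong_single − wrong_fused)/total`, rounded to one decimal.

## The synthetic generator

Molecular features are independent unit-variance Gaussians; a configurable
fraction (default 10%) is informative, each shifting the mean of exactly one
class by `effect_size` SD.  Missingness is missing-completely-at-random per
(patient, modality).  Slides are grids of tiles: a configured fraction is
near-white background (pixels clipped to [235, 255], so channel means are
guaranteed above the 220 filter), and tissue tiles draw a per-tile color
around a class mean with jitter `tile_color_sd` plus pixel noise, clamping
the darkest channel at 210 so the background filter always keeps them.  The
per-tile jitter emulates stain/region variability; without it tile-mean
colors would be trivially separable for any pixel-noise level, because the
mean over a tile's pixels averages pixel noise away.

The generator does **not** emulate count overdispersion, copy-number segment
structure, beta-value bimodality, feature correlation, or histology texture.
Passing tests therefore demonstrate that the machinery is correct and that
fusion behaves as designed when its assumptions hold — not performance on
real tumor cohorts.

## Study configurations

The bundled studies (`omifuse.studies`) fix desk-scale conditions:

* **Fusion benefit** — 200 patients/class, 4 molecular modalities with
  effect sizes 2.0 (RNA-Seq), 1.6 (miRNA-Seq), 0.8 (CNV), 1.2 (metDNA),
  100 features each, plus 3×3-tile slides of 32-px tiles; every modality
  missing for 10% of patients; 10-fold patient-wise CV.  Compared: fused
  weighted F1 on all samples vs. each modality on its own samples.
* **Weight recovery** — an oracle source (probability 1 on the truth) vs. a
  uniform-random source, n=500, 100 seeded repeats; success means the oracle
  holds the largest projected weight in every class row.
* **Selection recovery** — 200 patients/class, 200 features, 10% informative
  at effect size 1.0, screened at the beta-value defaults.

Weight training in the studies uses a step size of 0.05 (and 30 epochs for
the recovery study): with only a few hundred samples and minibatches of 32,
a 5-epoch run takes ~75 Adam steps, and a neural-network-scale step of 1e-3
could move the randomly initialized raw weights by at most ~0.075 — far less
than the typical init spread.  The library defaults remain 5 epochs and
lr 1e-3, batch size 32, validation fraction 0.10.

## Known limitations

* Fused scores are comparable across classes only through the shared
  convex-combination structure; they are not calibrated probabilities.
* mRMR's equal-width binning is scale-sensitive for long-tailed features.
* The weight optimizer sees in-sample training probabilities from the
  per-modality models; heavily overfit base models would bias the weights
  (the synthetic studies' SVMs are regularized by grid search, where this is
  benign).
* The slide pipeline expects already-rendered RGB images; pyramidal slide
  formats and magnification selection are out of scope.
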