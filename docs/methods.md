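# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, and what the synthetic cohort does and
does not establish about real data.

## The two-stage decision problem

Every subject receives the cheap screening test (fee `c_screen`, default
10 USD); subjects whose stage-1 score reaches the gate threshold `t` also
receive the confirmatory battery (fee `c_battery`, default 180 USD).  Total
cost is `n_all·c_screen + n_2·c_battery` with `n_2 = #{i : s1_i ≥ t}`.
Non-gated subjects are labelled negative — the screener can only rule out,
never diagnose.  Gated subjects take the stage-2 decision at a fixed 0.5
probability cut; only the gate threshold is swept.  The sweep is bounded
above by the screener's equal-error-rate threshold (where sensitivity and
specificity cross): beyond it the screener discards more cases than it keeps,
which no cost saving can justify.  The operating point is the **largest**
threshold whose F1 equals or exceeds the threshold-0 (gate-everyone)
reference — maximal saving at zero measured performance loss.  An optional
`f1_slack` relaxes the rule; the default is strict (0).

Two costing conventions coexist deliberately: the battery-alone *comparator*
is `n_all·c_battery` (no screening fee — the status quo where nobody is
screened), while the cascade itself always pays the screening fee for
everyone.  At `t = 0` the cascade therefore costs `n_all·(c_screen +
c_battery)`, slightly more than the comparator.

## Cost-sensitive loss and the class weight

Screening cohorts are heavily imbalanced (controls:cases ≈ 6–9:1).  The
training loss is the weighted cross-entropy with the positive term scaled by
`w_c = n_pos/n_neg` (≈ 0.163 at the default cohort composition), which
equalises the aggregate loss mass of the two classes and reduces to the
standard cross-entropy at `w_c = 1` (asserted to 1e-10 in the tests).
Predicted probabilities are clipped to `[1e-7, 1 − 1e-7]` inside the loss.
A consequence worth knowing: with `w_c < 1` the trained network's
probabilities are *down-shifted* relative to a calibrated model, so the
stage-2 cut of 0.5 is conservative early in training.

## Network architectures and training

Both classifiers are plain feed-forward networks implemented in numpy
(Dense, Conv2D with stride 1 and "same" padding via im2col, batch
normalisation, inverted dropout, ReLU, sigmoid head), trained with Adam
(lr 1e-3, batch 64 by default — unstated in the screening literature, so
ordinary defaults) and early stopping: training halts when the validation
loss has not improved for `patience` epochs and the best-epoch weights are
restored.  All randomness flows through `numpy.random.Generator`, so
training is bit-reproducible for a fixed seed.

* **Screener**: one hidden layer of 128 units on the 5-vector
  (age, sex, education, depression score, MMSE total); 897 parameters.
* **Battery CNN**: conv(128 filters, k=2) → conv(32, k=2) → two dense
  layers of 64 → sigmoid, with batch-norm after each convolution and
  dropout 0.1 in the head.  The *skip connection* concatenates the flattened
  input grid onto the convolutional features entering the first dense layer
  (concatenation, not addition — the two tensors have different widths), so
  per-variable values reach the head unmixed.  Disabling it removes exactly
  `grid_cells × 64` weights.

The hyper-parameter grid helper enumerates inclusive integer ranges —
conv layers 1–4, filters {32, 64, 128}, kernel 2–4, dense layers 1–4, hidden
units {32, 64, 128}, i.e. 432 candidate architectures — with filter and
hidden counts shared across layers of the same kind; the default spec above
(heterogeneous 128/32 filters) is exposed directly rather than through the
grid.

## Hilbert embedding

Convolutions need spatial locality; a tabular vector has none.  The battery
input (selected sub-scores in instrument order, demographics appended at the
tail) is laid out along the canonical Hilbert traversal of the smallest
`2^p × 2^p` grid with `4^p ≥ n_variables`; unused cells are padded with 0,
which is the column mean after z-scoring.  Orientation convention: the curve
starts at (0,0) and for order 1 visits (0,0), (1,0), (1,1), (0,1).  Any
fixed orientation would do; this one is frozen and tested.  Consecutive
variables always land on grid-adjacent cells (Manhattan distance 1), which
the row-major baseline violates once per row — the property tests assert the
strict adjacency advantage for sides ≥ 4.

## Imputation

* **MinMax** assumes missingness reflects the subject's inability to perform
  the item: a variable positively point-biserial-correlated with the
  diagnosis gets its observed maximum, a negatively correlated one its
  minimum.  Degenerate correlation (|r| < 1e-12, or a constant variable)
  falls back to the observed median — a case the rule itself does not cover.
* **kNN** (k = 5) averages the variable over the k nearest subjects that
  observe it.  Distances are Euclidean over co-observed, z-scored
  coordinates, rescaled by `sqrt(total/co-observed)` so subjects with many
  missing cells are not spuriously close.  Fewer than k eligible donors
  triggers a fallback to all donors plus a logged warning.
* **LLS** regresses each incomplete variable on its `k_vars = 10`
  most-|Pearson|-correlated peers and predicts by least squares; predictors
  missing in the target row are dropped and the model refit, and
  rank-deficient designs are solved minimum-norm.
* **MI** draws `m = 5` chained-regression completions (scikit-learn's
  iterative imputer with Bayesian-ridge posterior sampling, 10 sweeps, each
  regression restricted to the 30 most-correlated predictors) and averages
  them cellwise.  Posterior sampling supplies the between-imputation
  variability that predictive-mean matching would otherwise provide; the
  average is deterministic for a fixed seed.

Evaluation is dual.  *Direct*: artificial blanks are punched into the
complete rows, matching the per-variable frequencies of the real blanks,
and the restoration error is the Frobenius norm over masked cells (observed
cells are preserved exactly by construction, making the full-matrix and
masked-cell norms identical).  *Indirect*: six off-the-shelf classifiers
(logistic regression, random forest, gradient boosting, AdaBoost, bagging,
RBF-SVM) trained on complete rows score each imputer's completion of the
truly incomplete rows.  The winner has the best mean AUC rank across
classifiers, ties broken by direct error.  On the synthetic cohort the
regression-based imputers (LLS, MI) can edge out kNN because the generator's
Gaussian-copula structure is exactly linear; the robust pattern — nearest
neighbour error several times smaller than MinMax — holds across seeds.

## Variable selection

Only lowest-level sub-scores enter the ranking (the role tag enforces this;
subtotal or composite scores would make variables non-removable
independently).  Variables are discretised by equal-frequency binning into
10 bins (the information-theoretic criteria operate on discrete data; the
bin count trades bias against variance at cohort sample sizes).  Each of the
eight greedy criteria produces a full forward-selection ranking; the
CONDRED variant uses the conditional-redundancy form
`J = I(X;Y) + Σ_S I(X;X_s|Y)` from the unifying mutual-information
feature-selection framework.  Ranks are averaged; ties break by the best
single-criterion rank, then variable name — deterministic and documented.

Nested sets are scored by stratified cross-validated AUC with out-of-fold
scores retained, so the DeLong comparison against the best set is properly
paired.  Out-of-fold (rather than refit) predictions are used because the
paired test requires both score vectors on the same subjects.  The default
evaluation classifier is a logistic model — running the battery CNN inside
the per-size loop would be two orders of magnitude more expensive — with the
CNN reserved for final confirmation of the chosen set.  The selected set is
the smallest with DeLong p ≥ 0.05 against the best set; the best set always
qualifies (p = 1 against itself), so a selection always exists.

## Synthetic cohort: what it emulates, what it does not

The generator reproduces the *structure* the pipeline assumes: 3101
subjects with 2666 controls and 435 cases; four demographics with
label-shifted marginals (age +0.95 SD, education −0.42 SD, female odds
+0.33, depression +0.6 SD per unit effect size, matching published elderly
cohort tables loosely); an MMSE total with a 2.5-SD case shift (clinical
MMSE separation in dementia is large — controls ≈ 27 ± 2, cases typically
below 20 — and this default places the screener's discrimination near the
operating range a well-tuned screening network reaches); and 92 battery
sub-scores in 23 equicorrelated instrument blocks (ρ = 0.6) drawn from a
Gaussian copula and mapped to bounded 0–15 integer scores by rounding and
clipping.  40 sub-scores, spread evenly across blocks, carry a 1.0-SD
case shift by default.  All label shifts scale linearly with `effect_size`,
so `effect_size = 0` is an exact null cohort.

Missingness: ~75 of 3101 subjects lose 1–4 battery cells (mode 1–2), with
the first blank landing on one of two designated clock-drawing-style hotspot
variables with probability 0.85.  The mechanism is MCAR by default; a
configurable label tilt (`mar_label_shift`) makes cases likelier to be
affected.  The label and the MMSE total are never blanked, so stage 1 is
always computable.

What passing tests on this cohort do **not** show: real neuropsychological
scores are skewed, floor/ceiling-censored and nonlinearly related across
instruments; real missingness is informative in ways a label tilt does not
capture; and the linear copula structure flatters regression-based imputers
and linear classifiers alike.  Recovery results here are evidence the
*machinery* is correct, not forecasts of field performance.

## Numerical choices and degenerate inputs

- AUC is the tie-corrected rank statistic (ties count one half), identical
  to the trapezoidal ROC area; single-class inputs raise.
- The DeLong variance uses placement-value covariances with ddof 1;
  variance ≤ 1e-16 (e.g. identical score vectors) returns p = 1 rather than
  dividing by zero.
- Equal-error-rate candidates are midpoints between consecutive distinct
  scores plus the extremes, so perfectly separated scores return the gap
  midpoint and EER 0.
- Diagnostic metrics with zero denominators are reported as NaN
  ("undefined") instead of raising or silently propagating.
- Greedy-criterion score ties break toward the lower column index; exact
  ties are common on small discrete data (e.g. when the label is a
  deterministic function of a selected variable, every joint MI equals
  H(Y)).
- Reports round to 4 decimals; all internal arithmetic is double precision.

## Problem sizes used in the automated checks

The test suite and the acceptance script run the full 3101-subject cohort
for generation, imputation, ranking and the screener, and reduced sizes
where a full run adds nothing but wall-clock time: the battery CNN
cross-validation uses 3 folds at n = 2000 on the full 92-variable grid, the
planted-support selection and cascade recovery experiments use 20 seeds at
n = 1000, and the end-to-end pipeline smoke test runs 300 subjects with a
24-variable battery.  These sizes are the package's own choice of
experiment scale; the statistical conditions (imbalance, effect sizes,
correlation, missingness rates) are the defaults described above in every
case.
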