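# Methods

## Model and procedure

`confsol` wraps a gradient-boosted tree regressor (XGBoost, `hist` tree
method, single thread) in a cross-conformal prediction framework for
log-solubility.  The workflow is:

1. **Preprocessing.** Descriptors with any missing/non-finite value or a
   single unique value on the *training rows* are removed; survivors are
   mean-centred and scaled to unit sample SD (n−1 denominator), with all
   statistics taken from the training rows only.  Test and screening
   matrices are transformed with the training model unchanged, so nothing
   about the test distribution leaks into fitting.
2. **Sequential splitting.** Train/test splits take every p-th row at one
   or more 1-based offsets; nested rules can move designated members of an
   already-built test subset back to training (middle-set constructions for
   curated sets).  Splits operate on row order, which the CSV reader
   preserves exactly.
3. **Applicability domain.** k = round(k_fraction·n_train) (half-up,
   default fraction 0.375; 0.05 as the strict variant).  Threshold_i is the
   mean Euclidean distance of training sample i to its k nearest training
   neighbours, capped globally at RefVal = Q3 + 1.5·IQR of those means; a
   query is inside iff its distance to at least one training sample is ≤
   that sample's threshold.  The threshold rule is isolated in
   `ad.knn_thresholds` so an alternative rule can be swapped in without
   touching the decision logic.  The 0.5%-outside split-acceptance rule is
   reported (`split_approved` in the pipeline report), not looped: split
   selection is a data-curation act, not an optimisation.
4. **Tuning and FSTI selection.** Grid search over max_depth × eta with
   k-fold CV (every grid point on the same fold assignment, which is saved
   for reuse); the boosting-round count minimising the CV error up to
   `max_rounds` is kept.  FSTI ranks descriptors by total-gain importance
   of the all-variable winner, optionally drops rank-wise any descriptor
   with |Pearson r| above a threshold to an already-kept one, then
   cross-validates nested prefixes of size 3…m and beyond m until the
   RMSECV rises, selecting the global minimum.  The inner per-step grid is
   reduced (winner's depth ±1, coarse eta) by default; `full_inner_grid`
   restores the complete grid.  "Parallel" forward addition is read as
   candidate prefixes being evaluated independently, not as a different
   search order.
5. **Conformal calibration.** A repeated k-fold CV (defaults 20×20) gives
   each training compound n_repeats out-of-fold predictions; repeat 0 uses
   the saved tuning folds and its fold models are retained.  NC scores (see
   README table) are sorted descending; referents are taken at the
   99/95/90/80th percentiles.
6. **Validation, efficiency, classification.** Described in the README;
   classification of a screening set only proceeds when at least one
   configuration passes the error-rate t-test at some level.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| β (sensitivity) | grid {0, 0.5, 1.0, 1.5} | additive smoothing of the NC denominator, in multiples of the median calibration σ; β→∞ recovers constant-width behaviour, β=0 maximises per-compound adaptivity but risks degenerate denominators |
| n_folds / n_repeats | 20 / 20 | cross-conformal protocol; repeat r draws folds from seed master+r |
| k_fraction (AD) | 0.375 | neighbour share for the AD thresholds |
| m (FSTI cap) | 30 | largest prefix examined before the stop rule takes over |
| confidence grid | {99, 95, 90, 80}% | levels at which referents and intervals are produced; classification additionally needs {90, 80, 70}% |
| accuracy margin | 1 Log(S) | half-width boundary defining the accuracy classes |

## Numerical choices

- **Percentiles** use the nearest-rank convention (referent at level q =
  smallest score with at least q% of scores ≤ it); linear interpolation is
  available behind the `percentile_method="linear"` flag.  On 10 residuals
  0.1…1.0 the 80th-percentile referent is exactly 0.8.
- **β parameterisation**: multiples of the median calibration σ, so β
  transfers across data sets without pre-normalising descriptors into
  [−1, 1] (which would presume knowledge of the test range).
- **Degenerate denominators**: if σ + β·med σ = 0 for any calibration
  compound the engine raises with the offending IDs instead of jittering —
  silent jitter would corrupt the referents; the fix is raising β.
- **EM-Log zero residuals** are floored at 1e−6 before the log; far below
  experimental noise.  Stage-2 learners reuse the stage-1 hyperparameters
  and fold splits; σ̂ is the mean of the n_repeats out-of-fold stage-2
  predictions (exponentiated for the log variant), and a test compound's
  σ̂ averages all k × n_repeats stage-2 fold models.
- **t-test validation** builds the expected dummy vector with
  round(n·ε) ones (rounding unspecified in the source protocol; nearest is
  used).  Identical observed/expected vectors define p = 1.  Interval
  bounds count as inside — conservative for validity.
- **Ties**: neighbour ranking by row order (stable sort); grid ties break
  toward smallest nrounds, then depth, then eta; importance ties toward
  the earlier column.  Everything is deterministic under the master seed.
- **RMSE×t baseline** uses df = n_train − 1.
- **Accuracy profile**: bands between consecutive confidence levels get
  the midpoint accuracy and the difference of cumulative sub-margin
  fractions as weight.  The sliver above the highest probed level enters
  with that level's own accuracy only when its fraction is ≥ 0.05 —
  below that it is beyond the probing resolution and excluded, which is
  also why probing an extra level (e.g. 92%) refines rather than shifts
  the estimate.  Compounds over the margin at the lowest level are never
  counted.  If no compound is under the margin anywhere, the estimate
  falls back to the confidence level where the mean half-width crosses
  1 Log(S) (linear interpolation), flagged `degenerate`.

## Synthetic data: what it emulates and what it does not

The generator produces i.i.d. standard-normal descriptors, a linear signal
through a handful of informative columns (default effects 2.0, 1.5, 1.2,
0.9, 0.7 among 50 noise columns), and heteroscedastic Gaussian error with
SD = noise_base + noise_slope·|x_driver| (defaults 0.3 + 0.5·|driver|).
This mimics the two structural facts the method relies on: most candidate
descriptors are irrelevant, and prediction difficulty varies per compound
with an observable size-like driver — the average error SD (≈0.7 Log(S))
sits in the range of real aqueous-solubility models.  It does **not**
reproduce descriptor covariance structures, discrete/count descriptors,
fat-tailed solubility distributions, or assay noise; passing tests
therefore demonstrate the statistical machinery (coverage, efficiency,
informativeness, recovery), not chemical accuracy on real compounds.

## Study sizes

The seeded studies in `confsol.experiments` use 400 training / 200 test
compounds per seed (20 seeds for validity, first 10 for efficiency and
informativeness) and, for FSTI recovery, 500 compounds with 5 informative
among 55 descriptors over 10 seeds with a compact outer grid (depth
{2, 4} × eta {0.1, 0.3}, 60 rounds, m = 10).  These sizes give stable
verdicts for the binomial-style checks while keeping a full reproduction
run in the minutes range on one CPU; the conformal study ranks descriptors
once by total-gain importance and keeps the top 8, standing in for the
full FSTI stage whose behaviour the recovery study probes directly.

## Known limitations

- Cross-conformal validity is approximate, not finite-sample guaranteed
  (unlike split-conformal); the t-test validation is the operational
  check.
- AR's constant width means its residual-correlation is undefined by
  construction; the engine raises rather than returning NaN.
- The middle-set nested split reproduces the described construction rule;
  exact published memberships of historical splits are not asserted.
- The β grid is scanned, not optimised continuously; efficiency gains on
  strongly heteroscedastic data are modest at 80–90% levels and largest at
  99%, mirroring how referent percentiles interact with the σ estimate's
  own noise.
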