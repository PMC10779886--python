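# confsol

Per-compound prediction intervals for log-solubility (Log(S), log10 mol/L)
around gradient-boosted-tree QSPR models, with an applicability-domain gate
and interval-based accuracy estimation for screening sets that have no
experimental solubilities.

## Who it is for

Modellers in drug discovery and process development who need more than a
point estimate of aqueous or organic-solvent solubility: an individual
error margin per compound, a statistical proof that those margins hold
their nominal confidence, and a way to estimate how accurate a model will
be on an external database before any experiment is run.

## What it computes

**Cross-conformal prediction intervals.** In a cross-conformal predictor
every training compound doubles as a calibration compound.  A 20-time
repeated 20-fold CV gives each compound a set of out-of-fold predictions
with mean μ̂ and SD *s*.  Nonconformity (NC) scores are computed per
calibration compound, sorted descending, and their 99th/95th/90th/80th
percentiles become referent values α(conf):

| NC | score | test half-width |
|----|-------|-----------------|
| AR | α = \|y − ŷ\| | α(conf) — same for every compound |
| ARS | α = \|y − μ̂\| / (s + β·med s) | (β·med s + σ_TEST) × α(conf) |
| ARSS | α = \|y − ŷ₁\| / (s + β·med s) | (β·med s + σ_TEST) × α(conf) |
| EM-N / EM-Log | α = \|y − μ̂\| / (σ̂ + β·med σ̂), σ̂ from a second learner that predicts the (log-)absolute residual | (β·med σ̂ + σ̂_TEST) × α(conf) |
| kNN-EuD | α = \|y − μ̂\| / (d̄ + β·med d̄), d̄ = mean scaled distance to k nearest in-fold neighbours | (β·med d̄ + d̄_TEST) × α(conf) |
| RMSE×t | — | t(1 − ε/2, n−1) × RMSECV |

σ_TEST is the SD of the 20 saved fold-models' predictions for a test
compound, computed without its experimental value.  β, the sensitivity
coefficient, is expressed in multiples of the median calibration σ.
Intervals are symmetric: prediction ± half-width.

**Validity and efficiency.** The error rate (fraction of experimental
values outside their interval) is tested against the significance level
with an equal-variance t-test on inside/outside dummy vectors; p < 0.01
fails the configuration.  Efficiency is the median half-width Q2; the gain
of a normalized predictor over AR is Q2(AR)/Q2(CP) − 1.

**Applicability domain (AD).** A query compound is inside the AD when its
Euclidean distance (on training-scaled descriptors) to at least one
training compound falls under that compound's threshold — the mean
distance to its k nearest neighbours (k = 37.5% of the training set by
default), capped at Q3 + 1.5·IQR of those means.

**FSTI descriptor selection.** Descriptors are ranked by total-gain
importance of a grid-tuned booster; nested prefixes of size 3…m (m = 30,
optionally correlation-filtered at |r| > 0.9) are cross-validated and the
prefix at the global RMSECV minimum is selected.

**Accuracy classes.** Compounds whose 90% interval half-width is below
1 Log(S) fall in the "acc.>90%" class, below 1 at 80% in "80–90%", below 1
at 70% in "70–80%", else "acc.<70%".  Cumulative sub-margin fractions
across confidence levels, with midpoint accuracies per band, combine into
one estimated %LogS±1 for the whole screening set.

## Worked example

`python examples/04_conformal_intervals.py` trains on 400 synthetic
compounds (5 informative descriptors, heteroscedastic noise tied to a
molecular-weight-like driver) and predicts intervals for 200 test
compounds:

```
ARSS error rates (observed vs allowed, t-test at p<0.01):
  99%:   0.5% vs  1.0% -> valid (p = 0.563)
  95%:   4.0% vs  5.0% -> valid (p = 0.631)
  90%:  13.5% vs 10.0% -> valid (p = 0.278)
  80%:  26.5% vs 20.0% -> valid (p = 0.124)
median 90% half-width: ARSS 1.897 vs AR 1.922 Log(S) -> efficiency gain +1.3%
half-width vs |residual| correlation: R = 0.418 (p = 7e-10) — wider intervals
flag less reliable predictions
most precisely estimated compound: cmp_00512 Log(S) = -0.96 ± 1.272 (90% conf)
```

Every level is statistically valid (observed error rates never
significantly exceed the allowance), the normalized ARSS intervals are
narrower than the constant AR baseline at the median, and — unlike AR —
their widths correlate with the actual prediction errors, so a narrow
interval really does mean a more trustworthy prediction.

The other examples cover simulation and sequential splitting (01), the
applicability domain (02), FSTI selection (03), accuracy classes and
screening-set accuracy estimation (05), and the one-shot JSON-configured
pipeline (06).  The same functionality is scriptable via the `confsol`
CLI (`confsol simulate|split|ad|select|conformal|classify|profile|run|report`).

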