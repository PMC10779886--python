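"""Validity and efficiency assessment of conformal prediction intervals.

Validity: the fraction of test compounds whose experimental Log(S) falls
outside its interval (the error rate) should not significantly exceed the
significance level 1 − confidence.  The check is an equal-variance t-test
between the observed inside/outside dummy vector and an expected vector of
the same length holding exactly round(n·ε) ones; the configuration fails
validation when p < 0.01.

Efficiency: narrower intervals are better.  Q2 is the median half-width;
the gain of a normalized predictor over the constant-width AR baseline is
``Q2(AR)/Q2(CP) − 1``.  A normalized predictor is additionally
*informative* when its half-widths correlate positively with the absolute
residuals — wider intervals flag less reliable predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .conformal import IntervalSet
from .errors import DegenerateInputError, ParameterError, SchemaError

VALIDATION_ALPHA = 0.01


@dataclass
class LevelValidation:
    confidence: int
    error_rate: float
    expected_rate: float
    p_value: float
    passed: bool


@dataclass
class ValidationReport:
    """Per-confidence-level error rates with their t-test verdicts."""

    levels: dict[int, LevelValidation] = field(default_factory=dict)

    def passed_levels(self) -> list[int]:
        return sorted((lv for lv, r in self.levels.items() if r.passed), reverse=True)

    @property
    def all_failed(self) -> bool:
        return all(not r.passed for r in self.levels.values())


@dataclass
class EfficiencyEntry:
    config: str
    confidence: int
    median_hw: float
    mean_hw: float
    gain_vs_ar: float
    p_value_vs_ar: float


@dataclass
class EfficiencyReport:
    entries: list[EfficiencyEntry] = field(default_factory=list)

    def lookup(self, config: str, confidence: int) -> EfficiencyEntry:
        for e in self.entries:
            if e.config == config and e.confidence == confidence:
                return e
        raise KeyError((config, confidence))


def _outside_flags(intervals: IntervalSet, y_true: np.ndarray, level: int) -> np.ndarray:
    lo = intervals.lower[level]
    hi = intervals.upper[level]
    # boundary counts as inside (conservative for validity)
    return ((y_true < lo) | (y_true > hi)).astype(int)


def error_rate(intervals: IntervalSet, y_true: np.ndarray) -> dict[int, float]:
    """Fraction outside the interval per confidence level (bounds inclusive)."""
    y_true = np.asarray(y_true, dtype=float)
    if len(y_true) != len(intervals.ids):
        raise SchemaError("y_true length does not match the interval set")
    return {
        lv: float(_outside_flags(intervals, y_true, lv).mean())
        for lv in intervals.levels
    }


def validate_error_rate(
    outside_flags: np.ndarray, confidence: float
) -> tuple[float, bool]:
    """Equal-variance t-test of the observed error rate against expectation.

    The expected vector has the same length and exactly ``round(n·ε)``
    ones, ε = 1 − confidence.  Returns (p_value, passed); passed ⇔
    p ≥ 0.01.  Identical observed and expected vectors give p = 1.
    """
    if not 0.0 < confidence < 1.0:
        raise ParameterError(f"confidence must be in (0,1), got {confidence}")
    observed = np.asarray(outside_flags, dtype=float)
    n = len(observed)
    if n < 2:
        raise ParameterError("need at least 2 samples")
    n_ones = int(round(n * (1.0 - confidence)))
    expected = np.zeros(n)
    expected[:n_ones] = 1.0
    if observed.sum() == n_ones:
        return 1.0, True
    with warnings.catch_warnings():
        # near-constant dummy vectors are routine at high confidence levels
        warnings.simplefilter("ignore", RuntimeWarning)
        result = stats.ttest_ind(observed, expected, equal_var=True)
    p = float(result.pvalue)
    if np.isnan(p):
        p = 1.0
    return p, p >= VALIDATION_ALPHA


def validate_intervals(intervals: IntervalSet, y_true: np.ndarray) -> ValidationReport:
    """Full validation report across the interval set's confidence levels."""
    y_true = np.asarray(y_true, dtype=float)
    report = ValidationReport()
    for lv in intervals.levels:
        flags = _outside_flags(intervals, y_true, lv)
        p, passed = validate_error_rate(flags, lv / 100.0)
        report.levels[lv] = LevelValidation(
            confidence=lv,
            error_rate=float(flags.mean()),
            expected_rate=1.0 - lv / 100.0,
            p_value=p,
            passed=passed,
        )
    return report


def efficiency(
    intervals_by_config: dict[str, IntervalSet],
    ar_intervals: IntervalSet,
    paired: bool = False,
) -> EfficiencyReport:
    """Median/mean half-widths and gains of each configuration vs the AR baseline.

    gain = Q2(AR)/Q2(CP) − 1 at each level, with an (un)paired two-sample
    t-test on the half-width vectors against AR.
    """
    if not intervals_by_config:
        raise DegenerateInputError("no interval sets supplied")
    n_ref = len(ar_intervals.ids)
    report = EfficiencyReport()
    for config, ivs in intervals_by_config.items():
        if len(ivs.ids) != n_ref:
            raise SchemaError(f"config {config!r} covers a different test set")
        for lv in ivs.levels:
            hw = ivs.halfwidth[lv]
            ar_hw = ar_intervals.halfwidth[lv]
            q2_cp = float(np.median(hw))
            q2_ar = float(np.median(ar_hw))
            if np.allclose(hw, ar_hw):
                p = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    if paired:
                        p = float(stats.ttest_rel(hw, ar_hw).pvalue)
                    else:
                        p = float(stats.ttest_ind(hw, ar_hw, equal_var=True).pvalue)
            report.entries.append(
                EfficiencyEntry(
                    config=config,
                    confidence=lv,
                    median_hw=q2_cp,
                    mean_hw=float(np.mean(hw)),
                    gain_vs_ar=q2_ar / q2_cp - 1.0 if q2_cp > 0 else float("inf"),
                    p_value_vs_ar=p,
                )
            )
    return report


def select_optimal_cp(
    eff: EfficiencyReport,
    validations: dict[str, ValidationReport],
) -> tuple[dict[int, str], str]:
    """Winning configuration per confidence level, and overall.

    Per level: among configurations that passed validation at that level,
    the one with the smallest mean half-width.  Overall: the configuration
    minimising the unweighted average of its eight statistics (mean and
    median half-width at each of the four levels), restricted to
    configurations that passed validation at every level they report.
    Deterministic and independent of input order (ties break by config
    name).
    """
    levels = sorted({e.confidence for e in eff.entries}, reverse=True)
    per_level: dict[int, str] = {}
    for lv in levels:
        candidates = [
            e
            for e in eff.entries
            if e.confidence == lv
            and e.config in validations
            and lv in validations[e.config].levels
            and validations[e.config].levels[lv].passed
        ]
        if candidates:
            best = min(candidates, key=lambda e: (e.mean_hw, e.config))
            per_level[lv] = best.config

    overall_scores: dict[str, float] = {}
    for config in sorted({e.config for e in eff.entries}):
        report = validations.get(config)
        if report is None or any(not r.passed for r in report.levels.values()):
            continue
        entries = [e for e in eff.entries if e.config == config]
        stats_pool = [e.mean_hw for e in entries] + [e.median_hw for e in entries]
        overall_scores[config] = float(np.mean(stats_pool))
    if not per_level and not overall_scores:
        raise DegenerateInputError("no configuration passed validation at any level")
    overall = (
        min(overall_scores, key=lambda c: (overall_scores[c], c))
        if overall_scores
        else min(per_level.values())
    )
    return per_level, overall


def residual_interval_correlation(
    intervals: IntervalSet, y_true: np.ndarray, confidence: int = 90
) -> tuple[float, float, float]:
    """Pearson correlation of |residual| with half-width at one level.

    Returns (R, R², two-sided p).  Raises on constant half-widths (the AR
    baseline carries no per-compound information, so the correlation is
    undefined by construction).
    """
    y_true = np.asarray(y_true, dtype=float)
    hw = intervals.halfwidth[int(confidence)]
    if np.allclose(hw, hw[0]):
        raise DegenerateInputError(
            "half-widths are constant (AR-like); residual correlation undefined"
        )
    residual = np.abs(y_true - intervals.center)
    r, p = stats.pearsonr(residual, hw)
    return float(r), float(r) ** 2, float(p)
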