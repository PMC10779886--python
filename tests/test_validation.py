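"""Interval validity (error-rate t-test), efficiency and informativeness."""

import numpy as np
import pytest

from confsol import (
    build_intervals,
    efficiency,
    error_rate,
    residual_interval_correlation,
    select_optimal_cp,
    validate_error_rate,
)
from confsol.errors import DegenerateInputError, ParameterError, SchemaError
from confsol.validation import (
    LevelValidation,
    ValidationReport,
    validate_intervals,
)


def _intervals(center, hw_by_level, ids=None):
    center = np.asarray(center, dtype=float)
    ids = ids or [f"c{i}" for i in range(len(center))]
    return build_intervals(
        ids, center, {lv: np.asarray(h, dtype=float) for lv, h in hw_by_level.items()}
    )


def _report(passed_levels, failed_levels=()):
    rep = ValidationReport()
    for lv in passed_levels:
        rep.levels[lv] = LevelValidation(lv, 0.05, 0.1, 0.5, True)
    for lv in failed_levels:
        rep.levels[lv] = LevelValidation(lv, 0.5, 0.1, 0.001, False)
    return rep


# --- error rates ----------------------------------------------------------


def test_all_targets_at_centers_zero_error():
    ivs = _intervals([0.0, 1.0, 2.0], {90: [0.5] * 3, 80: [0.3] * 3})
    rates = error_rate(ivs, np.array([0.0, 1.0, 2.0]))
    assert rates == {90: 0.0, 80: 0.0}


def test_five_of_thirtysix_outside():
    """The 36-compound organic-solvent test case: 5 outside → 13.89%."""
    y = np.zeros(36)
    y[:5] = 10.0  # far outside
    ivs = _intervals(np.zeros(36), {90: np.ones(36)})
    rates = error_rate(ivs, y)
    assert rates[90] * 100 == pytest.approx(13.89, abs=0.01)


def test_boundary_counts_as_inside():
    ivs = _intervals([0.0], {90: [1.0]})
    assert error_rate(ivs, np.array([1.0]))[90] == 0.0
    assert error_rate(ivs, np.array([-1.0]))[90] == 0.0
    assert error_rate(ivs, np.array([1.0 + 1e-9]))[90] == 1.0


def test_error_rate_length_mismatch():
    ivs = _intervals([0.0], {90: [1.0]})
    with pytest.raises(SchemaError):
        error_rate(ivs, np.zeros(3))


# --- t-test validation ----------------------------------------------------


def test_observed_equals_expected_p_one():
    flags = np.zeros(50)
    flags[:5] = 1
    p, passed = validate_error_rate(flags, 0.9)  # expected 5 of 50
    assert p == 1.0 and passed


def test_methanol_case_passes():
    """5 of 36 outside at 90% is above 10% but not significant at 0.01."""
    flags = np.zeros(36)
    flags[:5] = 1
    p, passed = validate_error_rate(flags, 0.9)
    assert passed
    assert p > 0.01


def test_gross_violation_fails():
    """300 of 1000 outside at 99% confidence is a decisive failure."""
    flags = np.zeros(1000)
    flags[:300] = 1
    p, passed = validate_error_rate(flags, 0.99)
    assert not passed
    assert p < 1e-10


def test_confidence_bounds():
    with pytest.raises(ParameterError):
        validate_error_rate(np.zeros(10), 1.5)
    with pytest.raises(ParameterError):
        validate_error_rate(np.zeros(1), 0.9)


def test_error_rate_nonincreasing_in_confidence():
    """Nested intervals: higher confidence never has a higher error rate."""
    rng = np.random.default_rng(0)
    center = rng.standard_normal(200)
    y = center + rng.standard_normal(200)
    hw = {80: np.full(200, 1.28), 90: np.full(200, 1.64), 95: np.full(200, 1.96)}
    rates = error_rate(_intervals(center, hw), y)
    assert rates[95] <= rates[90] <= rates[80]


# --- efficiency -----------------------------------------------------------


def test_efficiency_gain_arithmetic():
    """Q2(AR)=1.2 vs Q2(CP)=1.0 → gain 0.2."""
    ar = _intervals(np.zeros(5), {90: [1.2] * 5})
    cp = _intervals(np.zeros(5), {90: [1.0] * 5})
    report = efficiency({"cp": cp}, ar)
    assert report.lookup("cp", 90).gain_vs_ar == pytest.approx(0.2)


def test_identical_to_ar_zero_gain_nonsignificant():
    ar = _intervals(np.zeros(5), {90: [1.2] * 5})
    report = efficiency({"same": ar}, ar)
    entry = report.lookup("same", 90)
    assert entry.gain_vs_ar == 0.0
    assert entry.p_value_vs_ar == 1.0


def test_efficiency_requires_same_test_set():
    ar = _intervals(np.zeros(5), {90: [1.0] * 5})
    cp = _intervals(np.zeros(4), {90: [1.0] * 4})
    with pytest.raises(SchemaError):
        efficiency({"cp": cp}, ar)
    with pytest.raises(DegenerateInputError):
        efficiency({}, ar)


# --- optimal-CP selection -------------------------------------------------


def test_single_config_wins_everywhere():
    ar = _intervals(np.zeros(5), {90: [1.0] * 5, 80: [0.8] * 5})
    eff = efficiency({"only": ar}, ar)
    per_level, overall = select_optimal_cp(eff, {"only": _report([90, 80])})
    assert per_level == {90: "only", 80: "only"}
    assert overall == "only"


def test_per_level_winners_differ():
    ar = _intervals(np.zeros(5), {90: [2.0] * 5, 80: [2.0] * 5})
    a = _intervals(np.zeros(5), {90: [1.5] * 5, 80: [0.5] * 5})
    b = _intervals(np.zeros(5), {90: [1.0] * 5, 80: [1.0] * 5})
    eff = efficiency({"A": a, "B": b}, ar)
    validations = {"A": _report([90, 80]), "B": _report([90, 80])}
    per_level, _ = select_optimal_cp(eff, validations)
    assert per_level == {90: "B", 80: "A"}


def test_failed_validation_excluded_at_that_level():
    ar = _intervals(np.zeros(5), {90: [2.0] * 5})
    a = _intervals(np.zeros(5), {90: [0.5] * 5})
    b = _intervals(np.zeros(5), {90: [1.0] * 5})
    eff = efficiency({"A": a, "B": b}, ar)
    validations = {"A": _report([], failed_levels=[90]), "B": _report([90])}
    per_level, overall = select_optimal_cp(eff, validations)
    assert per_level[90] == "B"
    assert overall == "B"


def test_winner_matches_exhaustive_scan_and_order_invariance():
    rng = np.random.default_rng(4)
    ar = _intervals(np.zeros(20), {lv: np.full(20, 2.0) for lv in (99, 95, 90, 80)})
    configs = {}
    for name in ("c1", "c2", "c3"):
        configs[name] = _intervals(
            np.zeros(20),
            {lv: 0.5 + rng.random(20) for lv in (99, 95, 90, 80)},
        )
    validations = {n: _report([99, 95, 90, 80]) for n in configs}
    eff_fwd = efficiency(dict(configs), ar)
    eff_rev = efficiency(dict(reversed(list(configs.items()))), ar)
    _, overall_fwd = select_optimal_cp(eff_fwd, validations)
    _, overall_rev = select_optimal_cp(eff_rev, validations)
    assert overall_fwd == overall_rev
    # exhaustive oracle: average of the 8 statistics per config
    scores = {}
    for name, ivs in configs.items():
        pool = [np.mean(ivs.halfwidth[lv]) for lv in (99, 95, 90, 80)]
        pool += [np.median(ivs.halfwidth[lv]) for lv in (99, 95, 90, 80)]
        scores[name] = np.mean(pool)
    assert overall_fwd == min(scores, key=scores.get)


def test_nothing_validated_raises():
    ar = _intervals(np.zeros(5), {90: [1.0] * 5})
    eff = efficiency({"A": ar}, ar)
    with pytest.raises(DegenerateInputError):
        select_optimal_cp(eff, {"A": _report([], failed_levels=[90])})


# --- informativeness ------------------------------------------------------


def test_halfwidth_proportional_to_residual_r_one():
    rng = np.random.default_rng(9)
    center = np.zeros(50)
    y = rng.standard_normal(50)
    hw = 3.0 * np.abs(y - center)
    ivs = _intervals(center, {90: hw})
    r, r2, p = residual_interval_correlation(ivs, y, 90)
    assert r == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)


def test_constant_halfwidths_raise():
    ivs = _intervals(np.zeros(10), {90: [1.0] * 10})
    with pytest.raises(DegenerateInputError):
        residual_interval_correlation(ivs, np.ones(10), 90)


def test_validate_intervals_report_structure(small_split, small_tuned, small_cvp):
    from confsol import conformal_intervals

    train, test = small_split
    ivs = conformal_intervals(
        train.X, train.y, test.X, test.ids, small_tuned,
        nc_type="ARSS", beta=0.5, cvp=small_cvp,
    )
    rep = validate_intervals(ivs, test.y)
    assert set(rep.levels) == {99, 95, 90, 80}
    for r in rep.levels.values():
        assert 0 <= r.error_rate <= 1
        assert r.passed == (r.p_value >= 0.01)
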