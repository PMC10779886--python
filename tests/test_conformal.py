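"""Conformal engine: CV predictions, NC scores, σ_TEST, interval assembly."""

import numpy as np
import pandas as pd
import pytest

from confsol import (
    SynthSpec,
    build_intervals,
    conformal_intervals,
    generate_dataset,
    interval_halfwidth,
    nc_em,
    nc_knn_eud,
    nc_scores,
    repeated_cv_predictions,
    rmse_t_profile,
    sigma_test,
    worked_fixture,
)
from confsol.conformal import (
    CrossValPredictions,
    NCProfile,
    referent_percentile,
)
from confsol.errors import (
    DataError,
    DegenerateNormalizationError,
    ParameterError,
    StateError,
)
from confsol.selection import TunedLearnerSpec, make_fold_assignment
from scipy import stats


def _fake_cvp(matrix):
    matrix = np.asarray(matrix, dtype=float)
    return CrossValPredictions(
        matrix=matrix,
        mu=matrix.mean(axis=1),
        s=matrix.std(axis=1, ddof=1),
        first_run=matrix[:, 0],
        fold_models=[],
        fold_assignments=[],
    )


# --- repeated CV ----------------------------------------------------------


def test_repeated_cv_mu_and_s_match_direct_recomputation(small_cvp):
    np.testing.assert_allclose(small_cvp.mu, small_cvp.matrix.mean(axis=1))
    np.testing.assert_allclose(
        small_cvp.s, small_cvp.matrix.std(axis=1, ddof=1)
    )
    assert small_cvp.matrix.shape[1] == 5
    assert len(small_cvp.fold_models) == 5


def test_constant_target_gives_zero_prediction_spread():
    """A constant Log(S) is predicted identically by every fold model."""
    X = pd.DataFrame({"a": np.random.default_rng(0).standard_normal(40)})
    y = np.full(40, -2.5)
    spec = TunedLearnerSpec(
        max_depth=2, eta=0.3, nrounds=10,
        cv_fold_assignment=make_fold_assignment(40, 4, 0), seed=0,
    )
    cvp = repeated_cv_predictions(X, y, spec, n_repeats=3)
    np.testing.assert_allclose(cvp.s, 0.0, atol=1e-6)


def test_first_repeat_uses_saved_fold_assignment(small_split, small_tuned, small_cvp):
    assert np.array_equal(
        small_cvp.fold_assignments[0], small_tuned.cv_fold_assignment
    )


# --- NC scores ------------------------------------------------------------


def test_arss_arithmetic():
    """ARSS with β=0: α = |residual| / s exactly."""
    cvp = _fake_cvp([[1.0, 2.0], [0.0, 1.0]])
    # sample 0: first_run 1.0, s = SD([1,2]) = 0.7071...; y = 1.5 → ar 0.5
    y = np.array([1.5, 2.0])
    profile = nc_scores(cvp, y, "ARSS", beta=0.0)
    s0 = np.std([1.0, 2.0], ddof=1)
    assert profile.scores.max() == pytest.approx(
        max(0.5 / s0, 2.0 / np.std([0.0, 1.0], ddof=1))
    )


def test_arss_unit_ratio():
    """ar = 0.5 with σ = 0.5 and β = 0 gives α = 1 exactly."""
    cvp = _fake_cvp([[0.0, 0.5 * np.sqrt(2)]])  # SD of the pair is exactly 0.5
    y = np.array([0.5])  # first-run prediction 0 → ar = 0.5
    profile = nc_scores(cvp, y, "ARSS", beta=0.0)
    assert cvp.s[0] == pytest.approx(0.5)
    assert profile.scores[0] == pytest.approx(1.0)


def test_ar_nearest_rank_percentile():
    """AR on residuals 0.1..1.0: 80th-percentile referent is 0.8."""
    resid = np.arange(0.1, 1.01, 0.1)
    cvp = _fake_cvp(np.column_stack([resid, resid]))
    y = np.zeros(10)
    profile = nc_scores(cvp, y, "AR", levels=(99, 95, 90, 80))
    assert profile.referents[80] == pytest.approx(0.8)
    assert profile.referents[90] == pytest.approx(0.9)
    assert profile.referents[99] == pytest.approx(1.0)


def test_percentile_conventions():
    scores = np.arange(1.0, 11.0)
    assert referent_percentile(scores, 80) == 8.0
    assert referent_percentile(scores, 80, method="linear") == pytest.approx(
        np.percentile(scores, 80)
    )
    with pytest.raises(ParameterError):
        referent_percentile(scores, 80, method="median_unbiased")


def test_ars_vs_arss_numerators():
    """ARS uses |y − μ̂|, ARSS uses |y − ŷ₁|; denominators agree."""
    cvp = _fake_cvp([[1.0, 3.0], [0.0, 2.0]])
    y = np.array([0.0, 4.0])
    ars = nc_scores(cvp, y, "ARS", beta=0.0)
    arss = nc_scores(cvp, y, "ARSS", beta=0.0)
    mu_res = np.abs(y - cvp.mu)
    first_res = np.abs(y - cvp.first_run)
    np.testing.assert_allclose(np.sort(ars.scores), np.sort(mu_res / cvp.s))
    np.testing.assert_allclose(np.sort(arss.scores), np.sort(first_res / cvp.s))


def test_zero_denominator_raises_with_ids():
    cvp = _fake_cvp([[1.0, 1.0], [0.0, 2.0]])  # s[0] = 0
    y = np.array([2.0, 1.0])
    with pytest.raises(DegenerateNormalizationError) as err:
        nc_scores(cvp, y, "ARSS", beta=0.0, ids=["aspirin", "caffeine"])
    assert "aspirin" in err.value.offending_ids


def test_referents_monotone_in_confidence(small_cvp, small_split):
    train, _ = small_split
    profile = nc_scores(small_cvp, train.y, "ARSS", beta=0.5)
    assert (
        profile.referents[99]
        >= profile.referents[95]
        >= profile.referents[90]
        >= profile.referents[80]
    )


# --- error models ---------------------------------------------------------


@pytest.fixture(scope="module")
def em_setup():
    table = generate_dataset(
        SynthSpec(
            n_samples=150, n_informative=2, n_noise=4,
            effect_sizes=(2.0, 1.0), noise_base=0.2, noise_slope=0.8, seed=17,
        )
    )
    spec = TunedLearnerSpec(
        max_depth=3, eta=0.3, nrounds=30,
        cv_fold_assignment=make_fold_assignment(150, 5, 17), seed=17,
    )
    return table, spec


def test_em_sigma_tracks_true_noise_scale(em_setup):
    """On heteroscedastic data the EM σ rank-correlates with the true SD."""
    table, spec = em_setup
    from confsol.synthetic import true_noise_sd

    _, predict_sigma = nc_em(table.X, table.y, spec, variant="normal",
                             beta=0.3, n_repeats=5)
    sigma = predict_sigma(table.X)
    truth = true_noise_sd(
        SynthSpec(n_samples=150, n_informative=2, n_noise=4,
                  effect_sizes=(2.0, 1.0), noise_base=0.2, noise_slope=0.8,
                  seed=17),
        table,
    )
    rho, p = stats.spearmanr(sigma, truth)
    assert rho > 0 and p < 0.01


def test_em_homoscedastic_near_constant_sigma():
    """With homoscedastic noise the EM intervals track the AR widths."""
    table = generate_dataset(
        SynthSpec(
            n_samples=150, n_informative=2, n_noise=4,
            effect_sizes=(2.0, 1.0), noise_base=0.6, noise_slope=0.0, seed=19,
        )
    )
    spec = TunedLearnerSpec(
        max_depth=3, eta=0.3, nrounds=30,
        cv_fold_assignment=make_fold_assignment(150, 5, 19), seed=19,
    )
    tr = table.subset(range(0, 100))
    te = table.subset(range(100, 150))
    spec.cv_fold_assignment = make_fold_assignment(100, 5, 19)
    em = conformal_intervals(
        tr.X, tr.y, te.X, te.ids, spec, nc_type="EM-N", beta=0.5, n_repeats=5
    )
    ar = conformal_intervals(
        tr.X, tr.y, te.X, te.ids, spec, nc_type="AR", n_repeats=5
    )
    ratio = np.median(em.halfwidth[90]) / np.median(ar.halfwidth[90])
    assert 0.85 <= ratio <= 1.15


def test_em_log_floors_zero_residuals(em_setup):
    """A perfectly predictable constant target exercises the log floor:
    stage-1 residuals collapse to ~0 and EM-Log σ comes back near the floor
    instead of blowing up on log(0)."""
    table, spec = em_setup
    y_const = np.full(len(table), -2.0)
    profile, predict_sigma = nc_em(
        table.X, y_const, spec, variant="log", beta=1.0, n_repeats=3
    )
    sigma = predict_sigma(table.X)
    assert np.isfinite(profile.scores).all()
    assert np.all(sigma < 1e-4)


# --- kNN-EuD --------------------------------------------------------------


def test_knn_sigma_matches_brute_force():
    rng = np.random.default_rng(31)
    Z = rng.standard_normal((24, 3))
    y = rng.standard_normal(24)
    labels = make_fold_assignment(24, 4, 5)
    cvp = _fake_cvp(np.column_stack([y + 0.1, y - 0.1]))
    cvp.fold_assignments = [labels]
    profile, predict_sigma = nc_knn_eud(Z, y, cvp, k=3, beta=0.5)
    # brute-force all calibration σ and α values as the oracle
    sigma = _knn_sigma_all(Z, labels, 3)
    med = np.median(sigma)
    alphas = np.abs(y - cvp.mu) / (sigma + 0.5 * med)
    np.testing.assert_allclose(profile.scores, np.sort(alphas)[::-1])
    # test-σ against the full training set
    q = Z[:1] + 0.05
    dq = np.sqrt(((Z - q[0]) ** 2).sum(axis=1))
    assert predict_sigma(q)[0] == pytest.approx(np.sort(dq)[:3].mean())


def _knn_sigma_all(Z, labels, k):
    out = np.empty(len(Z))
    for i in range(len(Z)):
        train_idx = np.flatnonzero(labels != labels[i])
        d = np.sqrt(((Z[train_idx] - Z[i]) ** 2).sum(axis=1))
        out[i] = np.sort(d)[:k].mean()
    return out


def test_knn_k1_coincident_query_zero_distance():
    """A query coincident with a training point contributes distance 0."""
    rng = np.random.default_rng(13)
    Z = rng.standard_normal((12, 2))
    y = rng.standard_normal(12)
    labels = make_fold_assignment(12, 3, 1)
    cvp = _fake_cvp(np.column_stack([y + 0.1, y - 0.1]))
    cvp.fold_assignments = [labels]
    _, predict_sigma = nc_knn_eud(Z, y, cvp, k=1, beta=1.0)
    assert predict_sigma(Z[4:5])[0] == 0.0


def test_knn_dense_cluster_smaller_sigma_larger_alpha():
    """Equal residuals: a compound inside a dense cluster gets smaller σ and
    hence a larger NC score than an isolated one."""
    rng = np.random.default_rng(14)
    cluster = rng.standard_normal((11, 2)) * 0.05
    lone = np.array([[8.0, 8.0]])
    Z = np.vstack([cluster, lone])
    y = np.zeros(12)
    labels = make_fold_assignment(12, 3, 2)
    cvp = _fake_cvp(np.column_stack([y + 0.5, y + 0.7]))  # equal residuals 0.6
    cvp.fold_assignments = [labels]
    profile, predict_sigma = nc_knn_eud(Z, y, cvp, k=2, beta=0.0)
    sigma = np.array([predict_sigma(Z[i : i + 1])[0] for i in range(12)])
    assert sigma[:11].max() < sigma[11]
    # numerators are all 0.6, so α orders inversely to σ: the isolated
    # compound has the smallest score
    expected = np.abs(y - cvp.mu) / _knn_sigma_all(Z, labels, 2)
    assert profile.scores[-1] == pytest.approx(expected.min())
    assert expected.argmin() == 11


def test_knn_k_bound():
    Z = np.zeros((6, 2))
    cvp = _fake_cvp(np.zeros((6, 2)) + [[0.1, -0.1]])
    cvp.fold_assignments = [np.array([0, 0, 0, 1, 1, 1])]
    with pytest.raises(ParameterError):
        nc_knn_eud(Z, np.zeros(6), cvp, k=3, beta=1.0)


# --- σ_TEST and half-widths ----------------------------------------------


def test_sigma_test_matches_direct_sd(small_split, small_tuned, small_cvp):
    _, test = small_split
    st_vals = sigma_test(small_tuned, small_cvp.fold_models, test.X)
    direct = np.stack(
        [m.predict(test.X) for m in small_cvp.fold_models], axis=1
    ).std(axis=1, ddof=1)
    np.testing.assert_allclose(st_vals, direct)
    assert (st_vals >= 0).all()


def test_sigma_test_model_count_mismatch(small_split, small_tuned, small_cvp):
    _, test = small_split
    with pytest.raises(StateError):
        sigma_test(small_tuned, small_cvp.fold_models[:-1], test.X)


def test_halfwidth_arithmetic():
    """(β·med σ + σ_TEST) × referent: 0.5 × 2.0 → 1.0."""
    profile = NCProfile(
        nc_type="ARSS", beta=0.2, med_sigma=0.5,
        scores=np.array([2.0]), referents={90: 2.0},
    )
    hw = interval_halfwidth(profile, np.array([0.4]), 90)
    assert hw[0] == pytest.approx((0.2 * 0.5 + 0.4) * 2.0)  # = 1.0
    assert hw[0] == pytest.approx(1.0)


def test_ar_halfwidth_constant_across_compounds():
    profile = NCProfile(
        nc_type="AR", beta=0.0, med_sigma=0.0,
        scores=np.array([1.229]), referents={90: 1.229},
    )
    hw = interval_halfwidth(profile, None, 90, n_test=5)
    np.testing.assert_allclose(hw, 1.229)


def test_rmse_t_baseline():
    profile = rmse_t_profile(rmsecv=0.5, n_train=101, levels=(95,))
    expected = stats.t.ppf(0.975, 100) * 0.5
    assert profile.referents[95] == pytest.approx(expected)


def test_unknown_confidence_rejected():
    profile = rmse_t_profile(0.5, 50, levels=(95,))
    with pytest.raises(ParameterError):
        interval_halfwidth(profile, None, 42, n_test=3)


def test_large_beta_flattens_halfwidths(small_split, small_tuned, small_cvp):
    """As β grows the normalized half-widths converge to a constant."""
    train, test = small_split
    cvs = []
    for beta in (0.0, 50.0):
        ivs = conformal_intervals(
            train.X, train.y, test.X, test.ids, small_tuned,
            nc_type="ARSS", beta=beta, cvp=small_cvp,
        )
        hw = ivs.halfwidth[90]
        cvs.append(hw.std() / hw.mean())
    assert cvs[1] < cvs[0] * 0.2


# --- interval assembly ----------------------------------------------------


def test_worked_example_interval_bounds():
    ex = worked_fixture()
    ivs = build_intervals(
        ["1-pentanol"], np.array([ex.center]),
        {90: np.array([ex.halfwidths[90]])},
    )
    assert ivs.lower[90][0] == pytest.approx(-1.222)
    assert ivs.upper[90][0] == pytest.approx(0.382)
    ar = build_intervals(
        ["1-pentanol"], np.array([ex.center]),
        {90: np.array([ex.ar_halfwidths[90]])},
    )
    assert ar.lower[90][0] == pytest.approx(-1.649)
    assert ar.upper[90][0] == pytest.approx(0.809)


def test_zero_halfwidth_degenerate_interval():
    ivs = build_intervals(["x"], np.array([1.0]), {90: np.array([0.0])})
    assert ivs.lower[90][0] == ivs.upper[90][0] == 1.0


def test_negative_halfwidth_rejected():
    with pytest.raises(DataError):
        build_intervals(["x"], np.array([0.0]), {90: np.array([-0.1])})


def test_interval_symmetry_and_level_monotonicity(small_split, small_tuned, small_cvp):
    train, test = small_split
    ivs = conformal_intervals(
        train.X, train.y, test.X, test.ids, small_tuned,
        nc_type="ARSS", beta=0.5, cvp=small_cvp,
    )
    for lv in ivs.levels:
        np.testing.assert_allclose(
            ivs.upper[lv] - ivs.center, ivs.center - ivs.lower[lv], atol=1e-12
        )
    hw = ivs.halfwidth
    assert (hw[99] >= hw[95]).all()
    assert (hw[95] >= hw[90]).all()
    assert (hw[90] >= hw[80]).all()
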