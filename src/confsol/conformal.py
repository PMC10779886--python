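"""Cross-conformal prediction intervals for Log(S).

In a cross-conformal predictor every training sample doubles as a
calibration sample: a repeated k-fold CV yields, per sample, a set of
out-of-fold predictions whose mean μ̂ and SD *s* feed the nonconformity
(NC) scores.  Calibration NC scores are sorted descending and their 99th /
95th / 90th / 80th percentiles become the referent values; multiplying a
referent by a test compound's own normalization term produces that
compound's interval half-width, centred on its point prediction.

NC measures
-----------
AR        |y − ŷ|                       constant half-width baseline
ARS       |y − μ̂| / (s + β·med s)       mean-based, SD-normalized
ARSS      |y − ŷ₁| / (s + β·med s)      single-prediction numerator
EM-N      |y − μ̂| / (σ̂ + β·med σ̂)      σ̂ = mean of a second learner's
EM-Log                                   (log-)absolute-residual predictions
kNN-EuD   |y − μ̂| / (d̄ + β·med d̄)      d̄ = mean scaled distance to the k
                                         nearest in-fold training samples
RMSE×t    t(1−ε/2, df) × RMSECV          classical regression baseline

β, the sensitivity coefficient, is expressed throughout as a multiple of
the median calibration normalization value, so it transfers across data
sets without pre-normalizing the descriptors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import t as t_dist

from .errors import (
    DataError,
    DegenerateNormalizationError,
    ParameterError,
    StateError,
)
from .selection import TunedLearnerSpec, XGBLearner, make_fold_assignment
from .synthetic import DEFAULT_CONFIDENCE_LEVELS

NC_TYPES = ("AR", "ARS", "ARSS", "EM-N", "EM-Log", "kNN-EuD", "RMSExT")

#: Floor applied to absolute residuals before taking logs (EM-Log).
LOG_RESIDUAL_FLOOR = 1e-6


@dataclass
class CalibrationRecord:
    """Per-sample calibration quantities of the repeated CV."""

    id: str
    y: float
    y_hat_single: float
    mu_hat: float
    s: float


@dataclass
class CrossValPredictions:
    """Out-of-fold prediction matrix of the repeated k-fold CV.

    ``matrix`` is n_samples × n_repeats; repeat 0 uses the fold assignment
    saved at tuning time and its fold models are kept for σ_TEST.
    """

    matrix: np.ndarray
    mu: np.ndarray
    s: np.ndarray
    first_run: np.ndarray
    fold_models: list[XGBLearner]
    fold_assignments: list[np.ndarray]

    def records(self, y: np.ndarray, ids: Sequence[str] | None = None) -> list[CalibrationRecord]:
        ids = list(ids) if ids is not None else [str(i) for i in range(len(y))]
        return [
            CalibrationRecord(
                id=ids[i],
                y=float(y[i]),
                y_hat_single=float(self.first_run[i]),
                mu_hat=float(self.mu[i]),
                s=float(self.s[i]),
            )
            for i in range(len(y))
        ]


@dataclass
class NCProfile:
    """One conformal configuration: NC type, β and referent percentiles.

    ``beta`` is in multiples of the median calibration normalization value
    ``med_sigma``; ``scores`` are the calibration NC scores sorted
    descending; ``referents`` map confidence level (percent) to the
    percentile NC value.
    """

    nc_type: str
    beta: float
    med_sigma: float
    scores: np.ndarray
    referents: dict[int, float]
    rmsecv: float = float("nan")
    df: int = 0

    @property
    def beta_abs(self) -> float:
        """β on the σ scale (β × median calibration σ)."""
        return self.beta * self.med_sigma


@dataclass
class IntervalSet:
    """Per-compound prediction intervals at each confidence level."""

    ids: list[str]
    center: np.ndarray
    sigma_test: np.ndarray | None
    halfwidth: dict[int, np.ndarray]
    lower: dict[int, np.ndarray]
    upper: dict[int, np.ndarray]

    @property
    def levels(self) -> list[int]:
        return sorted(self.halfwidth, reverse=True)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"compound_id": self.ids, "pred_logS": self.center})
        if self.sigma_test is not None:
            frame["sigma_test"] = self.sigma_test
        for lv in sorted(self.halfwidth):
            frame[f"hw{lv}"] = self.halfwidth[lv]
        for lv in sorted(self.halfwidth):
            frame[f"lo{lv}"] = self.lower[lv]
            frame[f"hi{lv}"] = self.upper[lv]
        return frame


def repeated_cv_predictions(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: TunedLearnerSpec,
    n_repeats: int = 20,
) -> CrossValPredictions:
    """Repeat the k-fold CV ``n_repeats`` times; collect per-sample predictions.

    Repeat 0 reuses the fold assignment saved with ``spec`` (the split that
    won the grid search); repeat r draws fresh folds from seed
    ``spec.seed + r``.  μ̂ is the row mean and *s* the row SD (n−1) of the
    prediction matrix.  The repeat-0 fold models are retained: applied to a
    test matrix they yield the k predictions whose SD is σ_TEST.
    """
    y = np.asarray(y, dtype=float)
    n = len(X)
    n_folds = spec.n_folds
    if n_folds > n:
        raise ParameterError(f"n_folds={n_folds} exceeds n_samples={n}")
    if n_repeats < 2:
        raise ParameterError("n_repeats must be ≥ 2")
    matrix = np.empty((n, n_repeats), dtype=float)
    fold_models: list[XGBLearner] = []
    assignments: list[np.ndarray] = []
    for r in range(n_repeats):
        labels = (
            spec.cv_fold_assignment
            if r == 0
            else make_fold_assignment(n, n_folds, spec.seed + r)
        )
        assignments.append(labels)
        for f in range(n_folds):
            test_idx = np.flatnonzero(labels == f)
            train_idx = np.flatnonzero(labels != f)
            learner = XGBLearner(spec.max_depth, spec.eta, spec.nrounds, seed=spec.seed)
            learner.fit(X.iloc[train_idx], y[train_idx])
            matrix[test_idx, r] = learner.predict(X.iloc[test_idx])
            if r == 0:
                fold_models.append(learner)
    return CrossValPredictions(
        matrix=matrix,
        mu=matrix.mean(axis=1),
        s=matrix.std(axis=1, ddof=1),
        first_run=matrix[:, 0],
        fold_models=fold_models,
        fold_assignments=assignments,
    )


def referent_percentile(
    scores: np.ndarray, q: float, method: str = "nearest_rank"
) -> float:
    """Percentile of the NC scores at level ``q`` (percent).

    ``nearest_rank`` (default): smallest score with at least q% of scores
    ≤ it.  ``linear``: NumPy linear interpolation.
    """
    asc = np.sort(np.asarray(scores, dtype=float))
    if method == "nearest_rank":
        rank = max(1, math.ceil(q / 100.0 * len(asc)))
        return float(asc[min(rank, len(asc)) - 1])
    if method == "linear":
        return float(np.percentile(asc, q))
    raise ParameterError(f"unknown percentile method {method!r}")


def _profile_from_alphas(
    nc_type: str,
    beta: float,
    med_sigma: float,
    alphas: np.ndarray,
    levels: Sequence[int],
    percentile_method: str,
) -> NCProfile:
    scores = np.sort(alphas)[::-1]
    referents = {
        int(lv): referent_percentile(scores, lv, percentile_method) for lv in levels
    }
    return NCProfile(
        nc_type=nc_type,
        beta=beta,
        med_sigma=med_sigma,
        scores=scores,
        referents=referents,
    )


def _normalize(
    residual: np.ndarray,
    sigma: np.ndarray,
    beta: float,
    ids: Sequence[str] | None,
) -> tuple[np.ndarray, float]:
    med = float(np.median(sigma))
    denom = sigma + beta * med
    bad = np.flatnonzero(denom == 0.0)
    if bad.size:
        names = [ids[i] for i in bad] if ids is not None else bad.tolist()
        raise DegenerateNormalizationError(
            "σ + β·median(σ) is zero for some calibration samples; raise β "
            f"(offending: {names[:10]})",
            offending_ids=names,
        )
    return residual / denom, med


def nc_scores(
    cvp: CrossValPredictions,
    y: np.ndarray,
    nc_type: str,
    beta: float = 0.0,
    levels: Sequence[int] = DEFAULT_CONFIDENCE_LEVELS,
    ids: Sequence[str] | None = None,
    percentile_method: str = "nearest_rank",
) -> NCProfile:
    """Calibration NC profile for AR, ARS or ARSS.

    AR uses the plain absolute residual of the saved CV run (its referents
    are used directly as half-widths).  ARS normalizes |y − μ̂| and ARSS
    |y − ŷ₁| by ``s + β·median(s)`` with *s* the SD of the repeated CV
    predictions.
    """
    if beta < 0:
        raise ParameterError("beta must be ≥ 0")
    y = np.asarray(y, dtype=float)
    if nc_type == "AR":
        alphas = np.abs(y - cvp.first_run)
        return _profile_from_alphas("AR", beta, 0.0, alphas, levels, percentile_method)
    if nc_type == "ARS":
        residual = np.abs(y - cvp.mu)
    elif nc_type == "ARSS":
        residual = np.abs(y - cvp.first_run)
    else:
        raise ParameterError(f"nc_scores handles AR/ARS/ARSS, not {nc_type!r}")
    alphas, med = _normalize(residual, cvp.s, beta, ids)
    return _profile_from_alphas(nc_type, beta, med, alphas, levels, percentile_method)


def nc_em(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: TunedLearnerSpec,
    variant: str = "normal",
    beta: float = 0.0,
    n_repeats: int = 20,
    levels: Sequence[int] = DEFAULT_CONFIDENCE_LEVELS,
    ids: Sequence[str] | None = None,
    percentile_method: str = "nearest_rank",
) -> tuple[NCProfile, Callable[[pd.DataFrame], np.ndarray]]:
    """Error-model NC (EM-N / EM-Log) plus its test-σ predictor.

    Each repeat runs two CVs on the same fold split and the same
    hyperparameters: the first predicts Log(S) and yields absolute
    residuals; the second predicts those residuals (or their logarithm).
    σ for a calibration sample is the mean of its ``n_repeats`` out-of-fold
    stage-2 predictions (exponentiated for the log variant); for a test
    compound it is the mean over all stage-2 fold models — k × n_repeats
    predictions per compound.
    """
    if variant not in ("normal", "log"):
        raise ParameterError(f"variant must be 'normal' or 'log', got {variant!r}")
    if beta < 0:
        raise ParameterError("beta must be ≥ 0")
    y = np.asarray(y, dtype=float)
    n = len(X)
    n_folds = spec.n_folds
    stage1 = np.empty((n, n_repeats), dtype=float)
    stage2 = np.empty((n, n_repeats), dtype=float)
    stage2_models: list[XGBLearner] = []
    for r in range(n_repeats):
        labels = (
            spec.cv_fold_assignment
            if r == 0
            else make_fold_assignment(n, n_folds, spec.seed + r)
        )
        preds = np.empty(n, dtype=float)
        folds = [
            (np.flatnonzero(labels != f), np.flatnonzero(labels == f))
            for f in range(n_folds)
        ]
        for train_idx, test_idx in folds:
            learner = XGBLearner(spec.max_depth, spec.eta, spec.nrounds, seed=spec.seed)
            learner.fit(X.iloc[train_idx], y[train_idx])
            preds[test_idx] = learner.predict(X.iloc[test_idx])
        stage1[:, r] = preds
        ar = np.abs(y - preds)
        target = np.log(np.maximum(ar, LOG_RESIDUAL_FLOOR)) if variant == "log" else ar
        err_pred = np.empty(n, dtype=float)
        for train_idx, test_idx in folds:
            learner = XGBLearner(spec.max_depth, spec.eta, spec.nrounds, seed=spec.seed)
            learner.fit(X.iloc[train_idx], target[train_idx])
            err_pred[test_idx] = learner.predict(X.iloc[test_idx])
            stage2_models.append(learner)
        stage2[:, r] = err_pred

    sigma_cal = (
        np.exp(stage2).mean(axis=1) if variant == "log" else stage2.mean(axis=1)
    )
    # EM normalizes against a positive error estimate; clip stray negatives
    sigma_cal = np.maximum(sigma_cal, 0.0)
    mu = stage1.mean(axis=1)
    residual = np.abs(y - mu)
    alphas, med = _normalize(residual, sigma_cal, beta, ids)
    nc_type = "EM-N" if variant == "normal" else "EM-Log"
    profile = _profile_from_alphas(nc_type, beta, med, alphas, levels, percentile_method)

    def predict_sigma(X_test: pd.DataFrame) -> np.ndarray:
        preds = np.stack([m.predict(X_test) for m in stage2_models], axis=1)
        if variant == "log":
            preds = np.exp(preds)
        return np.maximum(preds.mean(axis=1), 0.0)

    return profile, predict_sigma


def nc_knn_eud(
    Z: np.ndarray,
    y: np.ndarray,
    cvp: CrossValPredictions,
    k: int,
    beta: float = 0.0,
    levels: Sequence[int] = DEFAULT_CONFIDENCE_LEVELS,
    ids: Sequence[str] | None = None,
    percentile_method: str = "nearest_rank",
) -> tuple[NCProfile, Callable[[np.ndarray], np.ndarray]]:
    """kNN-Euclidean-distance NC on the scaled selected descriptors.

    σ for a calibration sample is the mean, over the repeated CV loop, of
    its average distance to the k nearest samples in the fold-training
    portion; for a test compound it is the average distance to the k
    nearest samples of the full training set.  The numerator is |y − μ̂|
    from the same repeated CV.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    if k < 1:
        raise ParameterError("k must be ≥ 1")
    n = len(Z)
    D_full = cdist(Z, Z)
    sigma_sum = np.zeros(n, dtype=float)
    for labels in cvp.fold_assignments:
        for f in range(int(labels.max()) + 1):
            test_idx = np.flatnonzero(labels == f)
            train_idx = np.flatnonzero(labels != f)
            if k >= len(train_idx):
                raise ParameterError(
                    f"k={k} must be smaller than the fold-training size {len(train_idx)}"
                )
            block = D_full[np.ix_(test_idx, train_idx)]
            part = np.sort(block, axis=1)[:, :k]
            sigma_sum[test_idx] += part.mean(axis=1)
    sigma_cal = sigma_sum / len(cvp.fold_assignments)
    residual = np.abs(y - cvp.mu)
    alphas, med = _normalize(residual, sigma_cal, beta, ids)
    profile = _profile_from_alphas(
        "kNN-EuD", beta, med, alphas, levels, percentile_method
    )

    def predict_sigma(Z_test: np.ndarray) -> np.ndarray:
        Z_test = np.atleast_2d(np.asarray(Z_test, dtype=float))
        D = cdist(Z_test, Z)
        return np.sort(D, axis=1)[:, :k].mean(axis=1)

    return profile, predict_sigma


def rmse_t_profile(
    rmsecv: float,
    n_train: int,
    levels: Sequence[int] = DEFAULT_CONFIDENCE_LEVELS,
) -> NCProfile:
    """Classical RMSE×t baseline: half-width = t(1−ε/2, n−1) × RMSECV."""
    referents = {
        int(lv): float(t_dist.ppf(1 - (1 - lv / 100.0) / 2, n_train - 1) * rmsecv)
        for lv in levels
    }
    return NCProfile(
        nc_type="RMSExT",
        beta=0.0,
        med_sigma=0.0,
        scores=np.array([]),
        referents=referents,
        rmsecv=rmsecv,
        df=n_train - 1,
    )


def sigma_test(
    spec: TunedLearnerSpec, fold_models: list[XGBLearner], X_test: pd.DataFrame
) -> np.ndarray:
    """σ_TEST: per test compound, the SD of the saved fold models' predictions.

    Uses only the k models of the saved tuning split — never the
    experimental test solubilities.
    """
    if len(fold_models) != spec.n_folds:
        raise StateError(
            f"expected {spec.n_folds} fold models, got {len(fold_models)}"
        )
    preds = np.stack([m.predict(X_test) for m in fold_models], axis=1)
    return preds.std(axis=1, ddof=1)


def interval_halfwidth(
    profile: NCProfile,
    sigma_test_values: np.ndarray | None,
    confidence: int,
    n_test: int | None = None,
) -> np.ndarray:
    """Half-width vector at one confidence level.

    Normalized NC types: ``(β·med σ + σ_TEST) × referent``, where σ_TEST is
    the test value of the profile's own normalization (SD of fold-model
    predictions for ARS/ARSS, error-model σ for EM, mean kNN distance for
    kNN-EuD).  AR and RMSE×t give the same half-width to every compound.
    """
    confidence = int(confidence)
    if confidence not in profile.referents:
        raise ParameterError(
            f"confidence {confidence} not in profile levels {sorted(profile.referents)}"
        )
    referent = profile.referents[confidence]
    if profile.nc_type in ("AR", "RMSExT"):
        if n_test is None:
            if sigma_test_values is None:
                raise ParameterError("need n_test or sigma_test to size the output")
            n_test = len(sigma_test_values)
        return np.full(n_test, referent, dtype=float)
    if sigma_test_values is None:
        raise ParameterError(f"{profile.nc_type} requires per-compound σ_TEST values")
    return (profile.beta_abs + np.asarray(sigma_test_values, dtype=float)) * referent


def build_intervals(
    ids: Sequence[str],
    center: np.ndarray,
    halfwidths: dict[int, np.ndarray],
    sigma_test_values: np.ndarray | None = None,
) -> IntervalSet:
    """Assemble an :class:`IntervalSet`: bounds = center ∓ half-width."""
    center = np.asarray(center, dtype=float)
    ids = list(ids)
    if len(ids) != len(center):
        raise DataError("ids and center lengths differ")
    hw: dict[int, np.ndarray] = {}
    lower: dict[int, np.ndarray] = {}
    upper: dict[int, np.ndarray] = {}
    for lv, values in halfwidths.items():
        values = np.asarray(values, dtype=float)
        if len(values) != len(center):
            raise DataError(f"half-width vector at {lv}% has wrong length")
        if (values < 0).any():
            raise DataError(f"negative half-width at {lv}% confidence")
        hw[int(lv)] = values
        lower[int(lv)] = center - values
        upper[int(lv)] = center + values
    return IntervalSet(
        ids=ids,
        center=center,
        sigma_test=None
        if sigma_test_values is None
        else np.asarray(sigma_test_values, dtype=float),
        halfwidth=hw,
        lower=lower,
        upper=upper,
    )


def conformal_intervals(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    test_ids: Sequence[str],
    spec: TunedLearnerSpec,
    nc_type: str = "ARSS",
    beta: float = 0.5,
    n_repeats: int = 20,
    levels: Sequence[int] = DEFAULT_CONFIDENCE_LEVELS,
    cvp: CrossValPredictions | None = None,
    Z_train: np.ndarray | None = None,
    Z_test: np.ndarray | None = None,
    knn_k: int = 5,
    percentile_method: str = "nearest_rank",
) -> IntervalSet:
    """End-to-end conformal intervals for one NC configuration.

    Runs (or reuses) the repeated CV, builds the calibration profile,
    computes the test normalization values appropriate to the NC type, and
    assembles symmetric intervals around the full-model point predictions.
    ``Z_train``/``Z_test`` (scaled matrices) are only needed for kNN-EuD.
    """
    if nc_type not in NC_TYPES:
        raise ParameterError(f"unknown NC type {nc_type!r}")
    y_train = np.asarray(y_train, dtype=float)
    if cvp is None:
        cvp = repeated_cv_predictions(X_train, y_train, spec, n_repeats=n_repeats)
    full = XGBLearner(spec.max_depth, spec.eta, spec.nrounds, seed=spec.seed)
    full.fit(X_train, y_train)
    center = full.predict(X_test)

    st = sigma_test(spec, cvp.fold_models, X_test)
    if nc_type in ("AR", "ARS", "ARSS"):
        profile = nc_scores(
            cvp, y_train, nc_type, beta, levels, percentile_method=percentile_method
        )
        norm_test = st
    elif nc_type in ("EM-N", "EM-Log"):
        profile, predict_sigma = nc_em(
            X_train,
            y_train,
            spec,
            variant="normal" if nc_type == "EM-N" else "log",
            beta=beta,
            n_repeats=n_repeats,
            levels=levels,
            percentile_method=percentile_method,
        )
        norm_test = predict_sigma(X_test)
    elif nc_type == "kNN-EuD":
        if Z_train is None or Z_test is None:
            raise ParameterError("kNN-EuD requires scaled Z_train and Z_test matrices")
        profile, predict_sigma = nc_knn_eud(
            Z_train, y_train, cvp, knn_k, beta, levels,
            percentile_method=percentile_method,
        )
        norm_test = predict_sigma(Z_test)
    else:  # RMSExT
        oof = cvp.first_run
        rmsecv = float(np.sqrt(np.mean((y_train - oof) ** 2)))
        profile = rmse_t_profile(rmsecv, len(X_train), levels)
        norm_test = None

    halfwidths = {
        int(lv): interval_halfwidth(profile, norm_test, lv, n_test=len(X_test))
        for lv in levels
    }
    return build_intervals(test_ids, center, halfwidths, sigma_test_values=st)
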