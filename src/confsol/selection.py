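"""Learner tuning and forward stepwise top-importance (FSTI) selection.

The learner is accessed through a minimal contract — ``fit``, ``predict``,
``importances`` — so the selection algorithm is learner-agnostic; the
default binding is a gradient-boosted tree regressor (XGBoost, ``hist``
tree method, single thread for determinism).

FSTI: (1) grid-optimise the learner on all descriptors and rank them by
total-gain importance; (2) optionally drop, in rank order, descriptors
whose absolute Pearson correlation with an already-kept descriptor exceeds
a threshold; (3) evaluate nested prefixes of size 3, 4, …, m with an inner
cross-validated grid search each; (4) beyond m, keep adding one descriptor
at a time until the cross-validation RMSE rises; (5) select the prefix at
the global RMSECV minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import xgboost as xgb

from .errors import DataError, DegenerateInputError, ParameterError, StateError


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid for the boosted-tree learner.

    The normal grid is ``max_depth`` 1–6 (step 1) × ``eta`` 0.1–1.0 (step
    0.1); the fine grid replaces the eta axis by 60 equidistant values in
    (0, 0.4].  ``max_rounds`` caps the boosting rounds searched; the
    round count minimising the CV error is kept.
    """

    max_depth_values: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    eta_values: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
    max_rounds: int = 200
    n_folds: int = 20
    fine_grid: bool = False

    def effective_eta_values(self) -> tuple[float, ...]:
        if self.fine_grid:
            return tuple(np.linspace(0.4 / 60, 0.4, 60))
        return self.eta_values


@dataclass
class TunedLearnerSpec:
    """Winning grid point plus the saved CV fold assignment.

    The fold assignment that produced the winning RMSECV is stored so the
    exact same split can be reused by the conformal stage.
    """

    max_depth: int
    eta: float
    nrounds: int
    cv_fold_assignment: np.ndarray
    seed: int
    rmsecv: float = float("nan")

    @property
    def n_folds(self) -> int:
        return int(self.cv_fold_assignment.max()) + 1


@dataclass
class SelectionResult:
    """Outcome of the FSTI forward search.

    ``selected_names`` is a prefix of ``ranked_names`` (after optional
    correlation filtering); ``rmsecv_path[i]`` is the RMSECV of the prefix
    of size ``sizes[i]``; ``stop_index`` points at the global minimum.
    """

    ranked_names: list[str]
    selected_names: list[str]
    rmsecv_path: list[float]
    sizes: list[int]
    stop_index: int
    tuned: TunedLearnerSpec | None = None


class XGBLearner:
    """Gradient-boosted tree regressor behind the minimal learner contract.

    Uses the native booster API (``hist`` tree method, one thread) so
    repeated small fits inside the cross-conformal loops stay cheap and
    bit-for-bit deterministic.
    """

    def __init__(self, max_depth: int, eta: float, nrounds: int, seed: int = 0):
        self.max_depth = int(max_depth)
        self.eta = float(eta)
        self.nrounds = int(nrounds)
        self.seed = int(seed)
        self._booster: xgb.Booster | None = None
        self._columns: list[str] | None = None

    def _params(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "eta": self.eta,
            "objective": "reg:squarederror",
            "tree_method": "hist",
            "nthread": 1,
            "seed": self.seed,
        }

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "XGBLearner":
        y = np.asarray(y, dtype=float)
        if not np.isfinite(y).all():
            raise DataError("target contains non-finite values")
        self._columns = list(X.columns)
        dtrain = xgb.DMatrix(
            X.to_numpy(dtype=float), label=y, feature_names=self._columns
        )
        self._booster = xgb.train(
            self._params(), dtrain, num_boost_round=self.nrounds
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self._booster is None:
            raise StateError("learner is not fitted")
        dmat = xgb.DMatrix(
            X[self._columns].to_numpy(dtype=float), feature_names=self._columns
        )
        return np.asarray(self._booster.predict(dmat), dtype=float)

    def importances(self) -> dict[str, float]:
        """Total-gain importance per descriptor; absent descriptors scored 0."""
        if self._booster is None:
            raise StateError("learner is not fitted")
        raw = self._booster.get_score(importance_type="total_gain")
        return {c: float(raw.get(c, 0.0)) for c in self._columns}


def make_fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Random near-equal fold labels 0..n_folds−1 for n samples."""
    if n_folds < 2 or n_folds > n:
        raise ParameterError(f"n_folds must be in 2..{n}, got {n_folds}")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_folds
    return labels[rng.permutation(n)]


def _folds_from_assignment(labels: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    return [
        (np.flatnonzero(labels != f), np.flatnonzero(labels == f))
        for f in range(int(labels.max()) + 1)
    ]


def _cv_rmse_curve(
    X: pd.DataFrame,
    y: np.ndarray,
    max_depth: int,
    eta: float,
    max_rounds: int,
    folds: list[tuple[np.ndarray, np.ndarray]],
    seed: int,
) -> tuple[int, float]:
    """Best (nrounds, RMSECV) along the boosting path for one grid point."""
    dtrain = xgb.DMatrix(X, label=y)
    params = {
        "max_depth": int(max_depth),
        "eta": float(eta),
        "objective": "reg:squarederror",
        "tree_method": "hist",
        "nthread": 1,
        "seed": int(seed),
    }
    history = xgb.cv(
        params,
        dtrain,
        num_boost_round=max_rounds,
        folds=folds,
        metrics="rmse",
        verbose_eval=False,
        seed=seed,
    )
    curve = history["test-rmse-mean"].to_numpy()
    best = int(np.argmin(curve))
    return best + 1, float(curve[best])


def grid_search_cv(
    X: pd.DataFrame, y: np.ndarray, grid: GridSpec, seed: int = 0
) -> TunedLearnerSpec:
    """Exhaustive grid search under k-fold CV; returns the winning spec.

    Every grid point is evaluated on the *same* fold assignment (derived
    from ``seed``), which is stored on the returned spec for reuse.
    Ties break toward the smallest nrounds, then max_depth, then eta.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise DataError("target contains non-finite values")
    if len(X) < grid.n_folds:
        raise ParameterError(
            f"need ≥ n_folds={grid.n_folds} samples, got {len(X)}"
        )
    labels = make_fold_assignment(len(X), grid.n_folds, seed)
    folds = _folds_from_assignment(labels)
    best: tuple[float, int, int, float] | None = None  # (rmse, nrounds, depth, eta)
    for depth in grid.max_depth_values:
        for eta in grid.effective_eta_values():
            nrounds, rmse = _cv_rmse_curve(
                X, y, depth, eta, grid.max_rounds, folds, seed
            )
            key = (rmse, nrounds, depth, eta)
            if best is None or key < best:
                best = key
    rmse, nrounds, depth, eta = best
    return TunedLearnerSpec(
        max_depth=depth,
        eta=eta,
        nrounds=nrounds,
        cv_fold_assignment=labels,
        seed=seed,
        rmsecv=rmse,
    )


def importance_ranking(learner: XGBLearner) -> list[str]:
    """Descriptor names by decreasing total-gain importance.

    Zero-importance descriptors are appended in their original column
    order; importance ties also break toward the earlier column.
    """
    imp = learner.importances()
    names = list(imp)
    order = sorted(range(len(names)), key=lambda i: (-imp[names[i]], i))
    return [names[i] for i in order]


def correlation_filter(
    X: pd.DataFrame, ranked: list[str], threshold: float
) -> list[str]:
    """Drop, in rank order, descriptors correlated above |r| > threshold
    with any already-kept descriptor (absolute Pearson, training rows)."""
    kept: list[str] = []
    for name in ranked:
        col = X[name].to_numpy(dtype=float)
        ok = True
        for prev in kept:
            r = np.corrcoef(col, X[prev].to_numpy(dtype=float))[0, 1]
            if np.isfinite(r) and abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(name)
    return kept


def _inner_grid(outer: TunedLearnerSpec, full: bool, base: GridSpec) -> GridSpec:
    """Grid used at each forward step: reduced around the all-variable winner
    (max_depth ±1, coarse eta) unless the full grid is requested."""
    if full:
        return base
    depths = tuple(
        d for d in (outer.max_depth - 1, outer.max_depth, outer.max_depth + 1)
        if 1 <= d <= 6
    )
    etas = tuple(sorted({0.1, 0.3, round(float(outer.eta), 10)}))
    return GridSpec(
        max_depth_values=depths,
        eta_values=etas,
        max_rounds=max(outer.nrounds, 10),
        n_folds=base.n_folds,
    )


def fsti_select(
    X: pd.DataFrame,
    y: np.ndarray,
    grid: GridSpec | None = None,
    m: int = 30,
    corr_threshold: float | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    full_inner_grid: bool = False,
) -> SelectionResult:
    """Forward stepwise top-importance descriptor selection.

    Ranks descriptors by grid-optimised importance, optionally applies the
    absolute-correlation filter, then walks nested prefixes (size 3 … m,
    and past m until the inner RMSECV rises) with a cross-validated grid
    search at every step.  The selected subset is the prefix at the global
    RMSECV minimum.
    """
    if grid is None:
        grid = GridSpec()
    if m < 3:
        raise ParameterError(f"m must be ≥ 3, got {m}")
    if len(X) < inner_folds:
        raise DegenerateInputError("fewer samples than inner folds")
    y = np.asarray(y, dtype=float)

    outer = grid_search_cv(X, y, grid, seed=seed)
    learner = XGBLearner(outer.max_depth, outer.eta, outer.nrounds, seed=seed).fit(X, y)
    ranked = importance_ranking(learner)
    candidates = (
        correlation_filter(X, ranked, corr_threshold)
        if corr_threshold is not None
        else list(ranked)
    )
    if len(candidates) < 3:
        raise DegenerateInputError(
            f"only {len(candidates)} usable descriptors after filtering; need ≥3"
        )

    inner = _inner_grid(outer, full_inner_grid, grid)
    inner = replace(inner, n_folds=inner_folds)
    m_eff = min(m, len(candidates))
    path: list[float] = []
    sizes: list[int] = []
    tuned_specs: list[TunedLearnerSpec] = []
    size = 3
    while size <= len(candidates):
        prefix = candidates[:size]
        spec = grid_search_cv(X[prefix], y, inner, seed=seed)
        path.append(spec.rmsecv)
        sizes.append(size)
        tuned_specs.append(spec)
        if size >= m_eff and len(path) >= 2 and path[-1] > path[-2]:
            break
        size += 1

    stop_index = int(np.argmin(path))
    selected = candidates[: sizes[stop_index]]
    return SelectionResult(
        ranked_names=ranked,
        selected_names=selected,
        rmsecv_path=path,
        sizes=sizes,
        stop_index=stop_index,
        tuned=tuned_specs[stop_index],
    )


def cv_predictions(
    X: pd.DataFrame, y: np.ndarray, spec: TunedLearnerSpec, labels: np.ndarray
) -> np.ndarray:
    """Out-of-fold predictions for one fold assignment (pooled CV vector)."""
    preds = np.empty(len(X), dtype=float)
    for train_idx, test_idx in _folds_from_assignment(labels):
        learner = XGBLearner(spec.max_depth, spec.eta, spec.nrounds, seed=spec.seed)
        learner.fit(X.iloc[train_idx], np.asarray(y)[train_idx])
        preds[test_idx] = learner.predict(X.iloc[test_idx])
    return preds


def evaluate_model(
    spec: TunedLearnerSpec,
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
) -> dict[str, float]:
    """Accuracy metrics: pooled RMSECV/R² (saved folds), RMSEV/R² on the
    test set, and %LogS within ±0.7 and ±1.0 (inclusive bounds)."""
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    if len(X_test) == 0:
        raise DegenerateInputError("empty test set")
    oof = cv_predictions(X_train, y_train, spec, spec.cv_fold_assignment)
    full = XGBLearner(spec.max_depth, spec.eta, spec.nrounds, seed=spec.seed)
    full.fit(X_train, y_train)
    pred = full.predict(X_test)
    res = np.abs(y_test - pred)
    return {
        "rmsecv": _rmse(y_train, oof),
        "rmsev": _rmse(y_test, pred),
        "r2_cv": _r2(y_train, oof),
        "r2_v": _r2(y_test, pred),
        "pct_logs_07": pct_within(res, 0.7),
        "pct_logs_10": pct_within(res, 1.0),
    }


def pct_within(abs_residuals: np.ndarray, threshold: float) -> float:
    """%LogS±threshold: share of |residuals| ≤ threshold (inclusive), percent."""
    abs_residuals = np.asarray(abs_residuals, dtype=float)
    return 100.0 * float((abs_residuals <= threshold).mean())


def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
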