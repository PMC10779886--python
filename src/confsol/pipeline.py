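"""End-to-end orchestration: split → preprocess → AD → select → conformal
→ validate → classify, driven by a single JSON config.

The run mirrors the four-step screening strategy: (a) prove model accuracy
on the held-out test set, (b) check the applicability-domain coverage of
the screening compounds, (c) calibrate and statistically validate the
conformal intervals, and (d) — only if validation succeeded at some level —
classify the screening compounds and estimate the overall accuracy.  Every
stage logs its effective parameters; a fixed master seed makes the whole
run deterministic.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import ad as ad_mod
from .classify import accuracy_profile, classify_compounds
from .conformal import conformal_intervals, repeated_cv_predictions
from .data import (
    SplitRule,
    apply_preprocessor,
    fit_preprocessor,
    read_table,
    sequential_split,
)
from .errors import ConfsolError, ParameterError
from .selection import GridSpec, evaluate_model, fsti_select, grid_search_cv
from .validation import efficiency, select_optimal_cp, validate_intervals


class SplitConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    period: int = 6
    start_offsets: list[int] = [2]


class ADConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_fraction: float = 0.375


class SelectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    m: int = 30
    corr_threshold: float | None = None
    inner_folds: int = 5


class GridConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_depth_values: list[int] = [1, 2, 3, 4, 5, 6]
    eta_values: list[float] = Field(
        default_factory=lambda: [round(0.1 * i, 10) for i in range(1, 11)]
    )
    max_rounds: int = 200
    n_folds: int = 20
    fine_grid: bool = False

    def to_spec(self) -> GridSpec:
        return GridSpec(
            max_depth_values=tuple(self.max_depth_values),
            eta_values=tuple(self.eta_values),
            max_rounds=self.max_rounds,
            n_folds=self.n_folds,
            fine_grid=self.fine_grid,
        )


class ConformalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    nc_types: list[str] = ["AR", "ARSS"]
    beta_grid: list[float] = [0.0, 0.5, 1.0]
    levels: list[int] = [99, 95, 90, 80]
    n_repeats: int = 20
    knn_k: int = 5

    @field_validator("beta_grid")
    @classmethod
    def _nonneg(cls, v):
        if any(b < 0 for b in v):
            raise ValueError("beta values must be ≥ 0")
        return v


class RunConfig(BaseModel):
    """Validated JSON run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    train_table: str
    test_table: str | None = None
    query_table: str | None = None
    split: SplitConfig | None = None
    ad: ADConfig = ADConfig()
    selection: SelectionConfig = SelectionConfig()
    grid: GridConfig = GridConfig()
    conformal: ConformalConfig = ConformalConfig()
    validation_alpha: float = 0.01
    output_dir: str = "confsol_run"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory.

    Writes intervals.csv, report.json, classes.csv, profile.json and
    run.log.  Classification is skipped (with a logged reason) when the
    conformal validation fails at every confidence level.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name: str, **params):
        log.append({"stage": name, "time": time.time(), **params})

    report: dict = {"config": config.model_dump()}

    # --- data ------------------------------------------------------------
    table = read_table(config.train_table)
    if config.test_table:
        train, test = table, read_table(config.test_table)
    else:
        rule = SplitRule(
            period=(config.split or SplitConfig()).period,
            start_offsets=tuple((config.split or SplitConfig()).start_offsets),
        )
        tr_idx, te_idx = sequential_split(table, rule)
        train, test = table.subset(tr_idx), table.subset(te_idx)
        stage("split", period=rule.period, offsets=list(rule.start_offsets),
              n_train=len(train), n_test=len(test))
    query = read_table(config.query_table, target_column=None) if config.query_table else test
    if train.y is None or test.y is None:
        raise ParameterError("train and test tables must carry the Log(S) target")
    stage("load", n_train=len(train), n_test=len(test), n_query=len(query))

    # --- preprocessing + AD ----------------------------------------------
    prep = fit_preprocessor(train)
    Z_train = apply_preprocessor(prep, train)
    Z_test = apply_preprocessor(prep, test)
    Z_query = apply_preprocessor(prep, query)
    ad_model = ad_mod.fit_ad(Z_train, config.ad.k_fraction)
    pct_test_outside = ad_mod.ad_coverage(ad_model, Z_test)
    pct_query_outside = ad_mod.ad_coverage(ad_model, Z_query)
    report["ad"] = {
        "k_neighbors": ad_model.k_neighbors,
        "pct_test_outside": pct_test_outside,
        "pct_query_outside": pct_query_outside,
        "split_approved": pct_test_outside < 0.5,
    }
    stage("ad", **report["ad"])

    # --- selection + tuning ----------------------------------------------
    grid = config.grid.to_spec()
    if config.selection.enabled and len(prep.kept_columns) > 3:
        sel = fsti_select(
            train.X[prep.kept_columns],
            train.y,
            grid=grid,
            m=config.selection.m,
            corr_threshold=config.selection.corr_threshold,
            inner_folds=config.selection.inner_folds,
            seed=config.seed,
        )
        selected = sel.selected_names
        report["selection"] = {
            "selected": selected,
            "rmsecv_path": sel.rmsecv_path,
            "sizes": sel.sizes,
        }
    else:
        selected = list(prep.kept_columns)
        report["selection"] = {"selected": selected}
    tuned = grid_search_cv(train.X[selected], train.y, grid, seed=config.seed)
    metrics = evaluate_model(
        tuned, train.X[selected], train.y, test.X[selected], test.y
    )
    report["model"] = {
        "max_depth": tuned.max_depth,
        "eta": tuned.eta,
        "nrounds": tuned.nrounds,
        **metrics,
    }
    stage("tune", **report["model"])

    # --- conformal calibration + validation ------------------------------
    levels = sorted(set(config.conformal.levels) | {90, 80, 70}, reverse=True)
    sel_cols = [c for c in prep.kept_columns if c in selected]
    col_pos = [prep.kept_columns.index(c) for c in sel_cols]
    cvp = repeated_cv_predictions(
        train.X[selected], train.y, tuned, n_repeats=config.conformal.n_repeats
    )
    interval_sets = {}
    for nc_type in config.conformal.nc_types:
        betas = [0.0] if nc_type in ("AR", "RMSExT") else config.conformal.beta_grid
        for beta in betas:
            key = f"{nc_type}(beta={beta:g})" if nc_type not in ("AR", "RMSExT") else nc_type
            interval_sets[key] = conformal_intervals(
                train.X[selected], train.y, test.X[selected], test.ids,
                tuned, nc_type=nc_type, beta=beta,
                n_repeats=config.conformal.n_repeats, levels=levels, cvp=cvp,
                Z_train=Z_train[:, col_pos], Z_test=Z_test[:, col_pos],
                knn_k=config.conformal.knn_k,
            )
    if "AR" not in interval_sets:
        interval_sets["AR"] = conformal_intervals(
            train.X[selected], train.y, test.X[selected], test.ids,
            tuned, nc_type="AR", beta=0.0, levels=levels, cvp=cvp,
        )
    validations = {k: validate_intervals(v, test.y) for k, v in interval_sets.items()}
    eff = efficiency(interval_sets, interval_sets["AR"])
    report["validation"] = {
        k: {
            str(lv): {
                "error_rate": r.error_rate,
                "p_value": r.p_value,
                "passed": r.passed,
            }
            for lv, r in v.levels.items()
        }
        for k, v in validations.items()
    }
    report["efficiency"] = [e.__dict__ for e in eff.entries]
    any_valid = any(not v.all_failed for v in validations.values())
    stage("conformal", configs=list(interval_sets), any_valid=any_valid)

    # --- classification ---------------------------------------------------
    if any_valid:
        per_level, overall_cfg = select_optimal_cp(eff, validations)
        report["optimal"] = {"per_level": {str(k): v for k, v in per_level.items()},
                             "overall": overall_cfg}
        query_intervals = conformal_intervals(
            train.X[selected], train.y, query.X[selected], query.ids,
            tuned,
            nc_type=overall_cfg.split("(")[0],
            beta=float(overall_cfg.split("beta=")[1].rstrip(")"))
            if "beta=" in overall_cfg else 0.0,
            n_repeats=config.conformal.n_repeats, levels=levels, cvp=cvp,
            Z_train=Z_train[:, col_pos], Z_test=Z_query[:, col_pos],
            knn_k=config.conformal.knn_k,
        )
        query_intervals.to_frame().to_csv(out / "intervals.csv", index=False)
        classes = classify_compounds(query_intervals)
        classes.to_frame().to_csv(out / "classes.csv", index=False)
        profile = accuracy_profile(query_intervals)
        report["profile"] = {
            "fractions": {str(k): v for k, v in profile.fractions.items()},
            "band_accuracies": profile.band_accuracies,
            "band_fractions": profile.band_fractions,
            "overall_accuracy": profile.overall_accuracy,
            "degenerate": profile.degenerate,
        }
        report["winner_intervals_config"] = overall_cfg
        stage("classify", overall_accuracy=profile.overall_accuracy)
    else:
        report["profile"] = None
        stage("classify", skipped=True,
              reason="conformal validation failed at every level")

    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_safe))
    (out / "run.log").write_text(
        "\n".join(json.dumps(entry, default=_json_safe) for entry in log)
    )
    return out


def _json_safe(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    report_path = run_dir / "report.json"
    if not report_path.exists():
        raise ConfsolError(f"incomplete run: missing {report_path}")
    report = json.loads(report_path.read_text())
    lines = ["confsol run summary", "===================="]
    model = report.get("model", {})
    if model:
        lines.append(
            f"model: depth={model.get('max_depth')} eta={model.get('eta')} "
            f"rounds={model.get('nrounds')}"
        )
        lines.append(
            f"RMSECV={model.get('rmsecv'):.3f}  RMSEV={model.get('rmsev'):.3f}  "
            f"R2(CV)={model.get('r2_cv'):.3f}  R2(V)={model.get('r2_v'):.3f}"
        )
        lines.append(
            f"%LogS±0.7={model.get('pct_logs_07'):.1f}%  "
            f"%LogS±1.0={model.get('pct_logs_10'):.1f}%"
        )
    ad_part = report.get("ad", {})
    if ad_part:
        lines.append(
            f"AD: k={ad_part.get('k_neighbors')}  "
            f"test outside={ad_part.get('pct_test_outside'):.2f}%  "
            f"query outside={ad_part.get('pct_query_outside'):.2f}%"
        )
    for cfg, levels in report.get("validation", {}).items():
        rates = "  ".join(
            f"{lv}%: {v['error_rate']:.3f}{'' if v['passed'] else ' (FAILED)'}"
            for lv, v in sorted(levels.items(), key=lambda kv: -int(kv[0]))
        )
        lines.append(f"error rates [{cfg}]: {rates}")
    profile = report.get("profile")
    if profile:
        lines.append(f"estimated %LogS±1 accuracy: {profile['overall_accuracy']:.1f}%")
    elif "validation" in report:
        lines.append("classification skipped: validation failed at every level")
    return "\n".join(lines)
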