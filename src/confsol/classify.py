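"""Interval-based accuracy classes and screening-set accuracy estimation.

For compounds without experimental solubilities, the only handle on
prediction accuracy is the interval half-width.  A compound whose 90%
interval is narrower than ±1 Log(S) has an estimated chance above 90% of
being predicted within one log unit, and so on down the confidence grid —
giving four accuracy classes.  Aggregating the cumulative fractions of
compounds under the 1-Log(S) margin at several confidence levels, with each
inter-level band assigned the midpoint accuracy, yields a single estimated
%LogS±1 for the whole screening set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conformal import IntervalSet
from .errors import DegenerateInputError, ParameterError

CLASS_LABELS = ("acc.>90%", "80–90%", "70–80%", "acc.<70%")

#: Half-width margin defining the accuracy classes, in Log(S) units.
MARGIN = 1.0

#: Top-band fractions below this are treated as beyond the probing
#: resolution and left out of the weighted accuracy estimate.
TOP_BAND_MIN_FRACTION = 0.05


@dataclass
class AccuracyClassTable:
    """Per-compound accuracy class plus the 80%-level half-width."""

    ids: list[str]
    class_label: list[str]
    halfwidth_80: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"compound_id": self.ids, "accuracy_class": self.class_label})
        if self.halfwidth_80 is not None:
            frame["hw80"] = self.halfwidth_80
        return frame


@dataclass
class AccuracyProfile:
    """Cumulative sub-margin fractions per level and the overall estimate.

    ``fractions[level]`` is the fraction of compounds whose half-width at
    that confidence level is below 1 Log(S); ``band_accuracies`` /
    ``band_fractions`` describe the inter-level bands; ``overall_accuracy``
    is their weighted mean in percent.
    """

    fractions: dict[int, float]
    band_accuracies: list[float]
    band_fractions: list[float]
    overall_accuracy: float
    degenerate: bool = False


def classify_compounds(intervals: IntervalSet) -> AccuracyClassTable:
    """Assign the four accuracy classes from half-widths at 90/80/70%.

    hw90 < 1 → "acc.>90%"; else hw80 < 1 → "80–90%"; else hw70 < 1 →
    "70–80%"; else "acc.<70%".
    """
    for lv in (90, 80, 70):
        if lv not in intervals.halfwidth:
            raise ParameterError(f"classification needs the {lv}% level")
    hw90 = intervals.halfwidth[90]
    hw80 = intervals.halfwidth[80]
    hw70 = intervals.halfwidth[70]
    labels = []
    for i in range(len(intervals.ids)):
        if hw90[i] < MARGIN:
            labels.append(CLASS_LABELS[0])
        elif hw80[i] < MARGIN:
            labels.append(CLASS_LABELS[1])
        elif hw70[i] < MARGIN:
            labels.append(CLASS_LABELS[2])
        else:
            labels.append(CLASS_LABELS[3])
    return AccuracyClassTable(
        ids=list(intervals.ids), class_label=labels, halfwidth_80=hw80.copy()
    )


def overall_from_bands(
    band_accuracies: Sequence[float], band_fractions: Sequence[float]
) -> float:
    """Weighted mean of band accuracies (fractions as weights), in percent.

    Accuracies may be given as fractions (0.85) or percents (85); the
    result is always a percentage.
    """
    acc = np.asarray(band_accuracies, dtype=float)
    frac = np.asarray(band_fractions, dtype=float)
    if acc.shape != frac.shape or acc.size == 0:
        raise ParameterError("band accuracies and fractions must align and be non-empty")
    if frac.sum() <= 0:
        raise DegenerateInputError("band fractions sum to zero")
    if np.all(acc <= 1.0):
        acc = acc * 100.0
    return float(np.sum(acc * frac) / np.sum(frac))


def accuracy_profile(
    intervals: IntervalSet, levels: Sequence[int] | None = None
) -> AccuracyProfile:
    """Estimate the screening set's overall %LogS±1 from interval widths.

    For each confidence level, take the fraction of compounds with
    half-width < 1 Log(S).  Bands between consecutive levels get the
    midpoint accuracy and the difference of cumulative fractions as
    weight.  The sliver above the highest probed level joins the average
    with the level's own accuracy only when its fraction reaches
    :data:`TOP_BAND_MIN_FRACTION`; compounds over the margin at the lowest
    level are excluded (they form the weakest class, not an estimate).

    If no compound is under the margin at any level, falls back to the
    confidence level at which the *mean* half-width equals 1 Log(S)
    (linear interpolation over the probed levels).
    """
    if levels is None:
        levels = [lv for lv in (90, 80, 70) if lv in intervals.halfwidth]
        levels += [lv for lv in intervals.halfwidth if lv not in levels]
    levels = sorted({int(lv) for lv in levels}, reverse=True)
    if len(levels) < 2:
        raise ParameterError("need at least two confidence levels")
    for lv in levels:
        if lv not in intervals.halfwidth:
            raise ParameterError(f"intervals lack the {lv}% level")

    fractions = {
        lv: float((intervals.halfwidth[lv] < MARGIN).mean()) for lv in levels
    }
    if all(f == 0.0 for f in fractions.values()):
        return _mean_halfwidth_fallback(intervals, levels, fractions)

    band_acc: list[float] = []
    band_frac: list[float] = []
    top = levels[0]
    if fractions[top] >= TOP_BAND_MIN_FRACTION:
        band_acc.append(top / 100.0)
        band_frac.append(fractions[top])
    for hi, lo in zip(levels, levels[1:]):
        width = fractions[lo] - fractions[hi]
        if width > 0:
            band_acc.append((hi + lo) / 200.0)
            band_frac.append(width)
    overall = overall_from_bands(band_acc, band_frac)
    return AccuracyProfile(
        fractions=fractions,
        band_accuracies=band_acc,
        band_fractions=band_frac,
        overall_accuracy=overall,
    )


def _mean_halfwidth_fallback(
    intervals: IntervalSet, levels: list[int], fractions: dict[int, float]
) -> AccuracyProfile:
    """Confidence level at which the mean half-width crosses 1 Log(S)."""
    means = {lv: float(np.mean(intervals.halfwidth[lv])) for lv in levels}
    asc = sorted(levels)  # mean half-width grows with confidence
    overall = float(asc[0])
    for lo, hi in zip(asc, asc[1:]):
        m_lo, m_hi = means[lo], means[hi]
        if m_lo <= MARGIN <= m_hi:
            frac = 0.0 if m_hi == m_lo else (MARGIN - m_lo) / (m_hi - m_lo)
            overall = lo + frac * (hi - lo)
            break
    else:
        overall = float(asc[0] if means[asc[0]] > MARGIN else asc[-1])
    return AccuracyProfile(
        fractions=fractions,
        band_accuracies=[],
        band_fractions=[],
        overall_accuracy=overall,
        degenerate=True,
    )


def combine_models(counts: Sequence[int], accuracies: Sequence[float]) -> float:
    """Count-weighted combination of per-model accuracy estimates (percent)."""
    counts = np.asarray(counts, dtype=float)
    accuracies = np.asarray(accuracies, dtype=float)
    if counts.shape != accuracies.shape or counts.size == 0:
        raise ParameterError("counts and accuracies must align and be non-empty")
    if (counts <= 0).any():
        raise ParameterError("counts must be positive")
    return float(np.sum(counts * accuracies) / np.sum(counts))


def export_predictions(
    ids: Sequence[str],
    smiles: Sequence[str] | None,
    weights: Sequence[float] | None,
    preds: Sequence[float],
    model_tag: str,
    hw80: Sequence[float],
    class_labels: Sequence[str],
    path: str | Path,
) -> None:
    """Write the seven-column screening export: id, SMILES, weight,
    prediction, model tag, 80% half-width, accuracy class."""
    n = len(ids)
    frame = pd.DataFrame(
        {
            "id": list(ids),
            "smiles": list(smiles) if smiles is not None else [""] * n,
            "mol_weight": list(weights) if weights is not None else [np.nan] * n,
            "pred_logS": list(preds),
            "model_tag": [model_tag] * n,
            "hw80": list(hw80),
            "accuracy_class": list(class_labels),
        }
    )
    frame.to_csv(path, index=False)
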