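"""Pixelwise segmentation performance measures and batch summaries.

Six measures from the TP/FP/FN/TN confusion counts of a predicted vs a
ground-truth lung mask: accuracy, overlap (Jaccard), sensitivity/recall,
specificity, precision and F-score. Ratios with a zero denominator are
reported as 0 and flagged, so every mask pair yields a full measure set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEASURE_NAMES = ("accuracy", "overlap", "sensitivity", "specificity", "precision", "f_score")

# overlay gray levels, per the confusion-matrix display convention:
# TN dark grey, TP light grey, FP white, FN black
OVERLAY_LEVELS = {"TN": 64, "TP": 192, "FP": 255, "FN": 0}


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MeasureSet:
    accuracy: float
    overlap: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    degenerate: tuple = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in MEASURE_NAMES}


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies of the four confusion categories."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float, name: str, degenerate: list) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def measures(c: ConfusionCounts) -> MeasureSet:
    """The six performance measures from one set of confusion counts."""
    if min(c.tp, c.fp, c.fn, c.tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    deg: list = []
    accuracy = _ratio(c.tp + c.tn, c.total, "accuracy", deg)
    overlap = _ratio(c.tp, c.tp + c.fp + c.fn, "overlap", deg)
    sensitivity = _ratio(c.tp, c.tp + c.fn, "sensitivity", deg)
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity", deg)
    precision = _ratio(c.tp, c.tp + c.fp, "precision", deg)
    f_score = _ratio(2.0 * precision * sensitivity, precision + sensitivity, "f_score", deg)
    return MeasureSet(
        accuracy=accuracy,
        overlap=overlap,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f_score=f_score,
        degenerate=tuple(deg),
    )


def evaluate(pred: np.ndarray, truth: np.ndarray) -> MeasureSet:
    """Convenience: measures straight from a mask pair."""
    return measures(confusion(pred, truth))


def summarize(measure_sets) -> pd.DataFrame:
    """Mean / sample std / min / max per measure over a batch.

    A single case reports std 0 (no dispersion measurable).
    """
    sets = list(measure_sets)
    if not sets:
        raise ValueError("cannot summarize an empty list of measures")
    table = pd.DataFrame([s.as_dict() for s in sets])
    std = table.std(ddof=1).fillna(0.0) if len(sets) > 1 else pd.Series(0.0, index=table.columns)
    return pd.DataFrame(
        {"mean": table.mean(), "std": std, "min": table.min(), "max": table.max()}
    )


def overlay(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """4-level uint8 visualization of the confusion categories."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    out = np.empty(pred.shape, dtype=np.uint8)
    out[~pred & ~truth] = OVERLAY_LEVELS["TN"]
    out[pred & truth] = OVERLAY_LEVELS["TP"]
    out[pred & ~truth] = OVERLAY_LEVELS["FP"]
    out[~pred & truth] = OVERLAY_LEVELS["FN"]
    return out
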