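"""Validation statistics: confusion matrix, precision and accuracy.

A model is scored against an expert-annotated validation set (one
presence/absence flag per recording).  The confusion matrix counts true
positives (present and detected), true negatives (absent and not
detected), false positives (absent but detected) and false negatives
(present but not detected); from it

    precision = TP / (TP + FP)
    accuracy  = (TP + TN) / total

Both are reported as percentages rounded half-up to the integer (the
convention of published validation tables, e.g. 67/68 = 98.5% -> 99)
with the unrounded value retained for programmatic use.  Precision is
undefined (reported missing) when the model makes no positive calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import pandas as pd

__all__ = ["ConfusionCounts", "Percent", "confusion", "precision", "accuracy",
           "round_half_up", "report"]


class Percent(NamedTuple):
    """A percentage statistic: integer (half-up) and exact value, or None."""

    rounded: int | None
    exact: float | None


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(
    validation: Mapping[str, bool],
    detections: Mapping[str, bool],
) -> ConfusionCounts:
    """Tally detections against expert truth over the validated recordings.

    Only validated recordings are scored; extra detections are ignored.

    Raises
    ------
    KeyError
        If a validated recording has no detection result (names it).
    """
    tp = fp = tn = fn = 0
    for rec_id, truth in validation.items():
        if rec_id not in detections:
            raise KeyError(f"no detection result for validated recording {rec_id!r}")
        detected = bool(detections[rec_id])
        if truth and detected:
            tp += 1
        elif truth:
            fn += 1
        elif detected:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def precision(c: ConfusionCounts) -> Percent:
    """TP / (TP + FP) as a percent; missing when no positive calls."""
    if c.tp + c.fp == 0:
        return Percent(None, None)
    exact = 100.0 * c.tp / (c.tp + c.fp)
    return Percent(round_half_up(exact), exact)


def accuracy(c: ConfusionCounts) -> Percent:
    """(TP + TN) / total as a percent.

    Raises
    ------
    ValueError
        If the validation set is empty (total = 0).
    """
    if c.n == 0:
        raise ValueError("accuracy undefined for an empty validation set")
    exact = 100.0 * (c.tp + c.tn) / c.n
    return Percent(round_half_up(exact), exact)


def report(
    validation: pd.DataFrame,
    detections: pd.DataFrame,
) -> pd.DataFrame:
    """Per-species validation report.

    ``validation`` columns: recording_id, species, present (0/1);
    ``detections`` columns: recording_id, species, present.  Returns one
    row per species: species, n, tp, fp, tn, fn, accuracy, precision
    (integer percents; precision empty when undefined).
    """
    rows = []
    for species, val in validation.groupby("species", sort=True):
        truth = {str(r): bool(p)
                 for r, p in zip(val["recording_id"], val["present"])}
        det = detections[detections["species"] == species]
        calls = {str(r): bool(p)
                 for r, p in zip(det["recording_id"], det["present"])}
        c = confusion(truth, calls)
        rows.append({
            "species": species, "n": c.n,
            "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
            "accuracy": accuracy(c).rounded,
            "precision": precision(c).rounded,
        })
    return pd.DataFrame(rows, columns=["species", "n", "tp", "fp", "tn", "fn",
                                       "accuracy", "precision"])
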