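"""Nucleotide-level evaluation of CRM predictions.

Predictions and truth are compared base by base: TP/TN/FP/FN counts feed the
Matthews-style correlation coefficient

    CC = (TP*TN - FP*FN) / sqrt((TP+FN)(FP+TN)(TP+FP)(TN+FN))

and precision / recall / F1. Counts are pooled across sequences by summation
(micro-averaging) before computing the pooled metrics; macro-averages over
per-sequence scores are reported as a secondary column. Degenerate
denominators yield NaN (flagged missing), never a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "cc_score",
    "f1_score",
    "pooled_metrics",
]

Interval = tuple[int, int]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def _union_length_and_mask(intervals: Iterable[Interval], seq_length: int):
    """Merged (sorted, overlapping-unioned) intervals; validates bounds."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[list[int]] = []
    for a, b in ivs:
        if a < 0 or b > seq_length or a > b:
            raise ValueError(f"interval [{a}, {b}) out of range [0, {seq_length})")
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return merged


def confusion_counts(
    predicted: Iterable[Interval], truth: Iterable[Interval], seq_length: int
) -> ConfusionCounts:
    """Per-nucleotide TP/TN/FP/FN between two half-open interval lists.

    Overlapping intervals within a list are unioned before counting.
    """
    pred = _union_length_and_mask(predicted, seq_length)
    true = _union_length_and_mask(truth, seq_length)
    # sweep over breakpoints of both interval sets
    events = sorted(
        {0, seq_length}
        | {x for iv in pred for x in iv}
        | {x for iv in true for x in iv}
    )
    tp = tn = fp = fn = 0

    def covered(merged, x):
        for a, b in merged:
            if a <= x < b:
                return True
            if a > x:
                break
        return False

    for a, b in zip(events[:-1], events[1:]):
        span = b - a
        p = covered(pred, a)
        t = covered(true, a)
        if p and t:
            tp += span
        elif p:
            fp += span
        elif t:
            fn += span
        else:
            tn += span
    return ConfusionCounts(tp, tn, fp, fn)


def cc_score(counts: ConfusionCounts) -> float:
    """Correlation coefficient in [-1, 1]; NaN when any marginal is zero."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fn) * (fp + tn) * (tp + fp) * (tn + fn)
    if denom == 0:
        return math.nan
    return (tp * tn - fp * fn) / math.sqrt(denom)


def f1_score(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1); undefined components are NaN, and F1 is 0 by
    convention when precision = recall = 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    pr = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    re = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    if math.isnan(pr) or math.isnan(re):
        f1 = math.nan
    elif pr == 0.0 and re == 0.0:
        f1 = 0.0
    else:
        f1 = 2.0 * pr * re / (pr + re)
    return pr, re, f1


def _row(counts: ConfusionCounts) -> dict:
    pr, re, f1 = f1_score(counts)
    return {
        "tp": counts.tp,
        "tn": counts.tn,
        "fp": counts.fp,
        "fn": counts.fn,
        "cc": cc_score(counts),
        "precision": pr,
        "recall": re,
        "f1": f1,
    }


def pooled_metrics(
    per_sequence_counts: Sequence[ConfusionCounts],
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sequence rows plus a pooled row (counts summed, then scored) and
    a macro row (mean of per-sequence scores, NaNs excluded)."""
    if not per_sequence_counts:
        raise ValueError("need at least one sequence")
    if names is None:
        names = [f"seq{i}" for i in range(len(per_sequence_counts))]
    rows = [{"sequence": nm, **_row(c)} for nm, c in zip(names, per_sequence_counts)]
    pooled = per_sequence_counts[0]
    for c in per_sequence_counts[1:]:
        pooled = pooled + c
    rows.append({"sequence": "pooled", **_row(pooled)})
    df = pd.DataFrame(rows).set_index("sequence")
    macro = df.iloc[:-1][["cc", "precision", "recall", "f1"]].mean()
    macro_row = {c: math.nan for c in df.columns}
    macro_row.update(macro.to_dict())
    df.loc["macro"] = macro_row
    return df
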