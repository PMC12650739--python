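"""Pixel-wise evaluation: confusion counts, accuracy, Dice, Jaccard,
per-method aggregation and a first-principles one-way ANOVA.

All three metrics derive from the same TP/TN/FP/FN tallies:

    accuracy = (TP + TN) / (TP + TN + FP + FN)
    Dice     = 2 TP / (2 TP + FP + FN)
    Jaccard  = TP / (TP + FP + FN)

with the identity Dice = 2 J / (1 + J). When both masks are empty, Dice
and Jaccard are defined as 1.0 (the two masks agree that nothing is
present) and the image is flagged as degenerate so aggregates can
exclude it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "ConfusionCounts", "MetricReport", "confusion", "accuracy", "dice",
    "jaccard", "evaluate_method", "anova_one_way",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies between a predicted and a true binary mask."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ParameterError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise DegenerateInputError("empty confusion counts")
    return (c.tp + c.tn) / c.total


def dice(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0  # both masks empty: agreement by convention
    return 2 * c.tp / denom


def jaccard(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


@dataclass
class MetricReport:
    """Per-image metrics plus mean ± sample SD per metric.

    ``per_image`` columns: image, accuracy, dice, jaccard, degenerate
    (True where both masks were empty or n = 1 made the SD undefined).
    ``summary`` columns: metric, mean, sd, n.
    """

    per_image: pd.DataFrame
    summary: pd.DataFrame


def evaluate_method(masks: list[tuple[np.ndarray, np.ndarray]],
                    ids=None) -> MetricReport:
    """Score a list of ``(pred, truth)`` pairs.

    SD is the sample standard deviation (n - 1 denominator); with a
    single image it is reported as 0 and the row flagged degenerate.
    """
    if not masks:
        raise ParameterError("evaluate_method needs at least one mask pair")
    ids = list(ids) if ids is not None else list(range(len(masks)))
    rows = []
    for img_id, (pred, truth) in zip(ids, masks):
        c = confusion(pred, truth)
        rows.append({
            "image": img_id,
            "accuracy": accuracy(c),
            "dice": dice(c),
            "jaccard": jaccard(c),
            "degenerate": (2 * c.tp + c.fp + c.fn) == 0 or len(masks) == 1,
        })
    per_image = pd.DataFrame(rows)
    n = len(per_image)
    summary_rows = []
    for metric in ("accuracy", "dice", "jaccard"):
        vals = per_image[metric].to_numpy()
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        summary_rows.append(
            {"metric": metric, "mean": float(vals.mean()), "sd": sd, "n": n}
        )
    return MetricReport(per_image=per_image, summary=pd.DataFrame(summary_rows))


def anova_one_way(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA from the sums-of-squares decomposition.

    ``F = MS_between / MS_within`` with ``df1 = k - 1``, ``df2 = N - k``;
    the p-value comes from the F survival function. Zero within-group
    variance with unequal means is reported as ``(inf, 0.0)``; all
    observations identical raises a degenerate-input error.
    """
    arrays = [np.asarray(g, dtype=np.float64).ravel() for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ParameterError("need >= 2 groups with >= 2 observations each")
    allvals = np.concatenate(arrays)
    if np.all(allvals == allvals[0]):
        raise DegenerateInputError("all observations identical")
    grand = allvals.mean()
    k = len(arrays)
    n_total = allvals.size
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0.0:
        return float("inf"), 0.0
    f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(sstats.f.sf(f_stat, df1, df2))
    return float(f_stat), p
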