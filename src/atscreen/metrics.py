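"""Workflow-comparison metrics.

Confusion-matrix summaries (sensitivity, specificity, accuracy), the mean
absolute percentage error between two quantification methods, and
Bland-Altman agreement limits. CHECK-style statuses count as negative when
confusion counts are built from screening hits in unsupervised mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .screening import ScreeningHit, Status


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def classification_metrics(c: ConfusionCounts, ndigits: int | None = None
                           ) -> tuple[float | None, float | None, float | None]:
    """(sensitivity, specificity, accuracy) = (TP/(TP+FN), TN/(TN+FP), (TN+TP)/n).

    A zero denominator yields None for that metric rather than zero.
    ``ndigits`` rounds at the reporting layer only.
    """
    sens = c.tp / (c.tp + c.fn) if c.tp + c.fn else None
    spec = c.tn / (c.tn + c.fp) if c.tn + c.fp else None
    acc = (c.tn + c.tp) / c.n
    if ndigits is not None:
        rnd = lambda v: None if v is None else round(v, ndigits)
        sens, spec, acc = rnd(sens), rnd(spec), rnd(acc)
    return sens, spec, acc


def confusion_from_hits(hits: list[ScreeningHit], truth: dict[tuple[str, str], bool],
                        check_positive: bool = False) -> ConfusionCounts:
    """Score screening hits against ground truth.

    In unsupervised mode CHECK (and masked) statuses count negative;
    ``check_positive`` flips CHECK to positive for the supervised
    re-evaluation scenario.
    """
    tp = tn = fp = fn = 0
    for h in hits:
        pos = h.status is Status.DETECTED or \
            (check_positive and h.status is Status.CHECK)
        true = truth[(h.analyte_id, h.sample_id)]
        if pos and true:
            tp += 1
        elif pos:
            fp += 1
        elif true:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def mape(ref, test) -> float:
    """Mean absolute percentage error of ``test`` against ``ref`` (percent)."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if len(ref) == 0:
        raise ValueError("MAPE of an empty comparison is undefined")
    if np.any(ref <= 0):
        raise ValueError("reference concentrations must be positive")
    return float(np.mean(np.abs(ref - test) / ref) * 100.0)


def bland_altman(ref, test, limit_multiplier: float = 1.96):
    """Bland-Altman agreement statistics between two methods.

    diff = test - ref; limits are mean(diff) +/- limit_multiplier * sd(diff)
    (sample standard deviation). Returns (mean_diff, lower, upper, pair_means,
    diffs) with the per-pair table ready for plotting.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if len(ref) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    diff = test - ref
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    means = (ref + test) / 2.0
    return (mean_diff, mean_diff - limit_multiplier * sd,
            mean_diff + limit_multiplier * sd, means, diff)
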