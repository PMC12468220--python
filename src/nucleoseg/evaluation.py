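"""Pixel-level segmentation metrics, PSNR, batch aggregation, paired t-test.

Masks are compared pixelwise (True = nucleus) to a ground-truth mask, giving
the confusion counts TP/FP/TN/FN and from them precision, recall
(sensitivity), F1 and accuracy.  Degenerate cases are resolved by convention
rather than NaN so batch tables stay numeric, and every convention use is
flagged:

* empty prediction (TP + FP = 0): precision = 1 (no false positives)
* empty truth and empty prediction: recall = 1 and F1 = 1
* precision + recall = 0: F1 = 0

PSNR is the standard 10*log10(MAX^2 / MSE) with MAX = 1 on the normalized
scale (+inf for identical images).  The paired t-test is the classical
statistic on per-trial differences with a two-sided p-value from the t
distribution with n-1 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "PairedTResult",
    "confusion",
    "metrics",
    "psnr",
    "paired_t_test",
    "evaluate_batch",
]

METRIC_COLUMNS = ["precision", "recall", "f1", "accuracy"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    precision: float
    recall: float
    f1: float
    accuracy: float
    psnr: float | None = None
    image: str | None = None
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PairedTResult:
    mean_difference: float
    t: float
    p: float
    df: int
    significant: bool  # at the 0.05 level
    flags: tuple[str, ...] = ()


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between prediction and ground truth."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts, image: str | None = None) -> MetricReport:
    """Precision, recall, F1 and accuracy with flagged degenerate conventions."""
    if c.total <= 0:
        raise ValueError("confusion counts are empty")
    flags: list[str] = []
    if c.tp + c.fp == 0:
        precision = 1.0
        flags.append("empty_prediction")
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        recall = 1.0
        flags.append("empty_truth")
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        f1 = 0.0
    elif c.tp == 0 and c.fn > 0:
        f1 = 0.0  # empty prediction against non-empty truth
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    accuracy = (c.tp + c.tn) / c.total
    return MetricReport(
        precision=precision, recall=recall, f1=f1, accuracy=accuracy,
        image=image, flags=tuple(flags),
    )


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB between two [0, 1] images."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(1.0 / mse)


def paired_t_test(a, b, alpha: float = 0.05) -> PairedTResult:
    """Classical paired t-test on per-trial differences ``a - b``.

    Zero-variance differences are degenerate: all-zero differences report
    t = 0, p = 1 (non-significant); a nonzero constant difference reports
    t = +/-inf, p = 0.  Both cases are flagged.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    flags: list[str] = []
    if sd == 0.0:
        if mean == 0.0:
            t, p = 0.0, 1.0
            flags.append("all_differences_zero")
        else:
            t = math.inf if mean > 0 else -math.inf
            p = 0.0
            flags.append("zero_variance")
    else:
        t = mean / (sd / math.sqrt(n))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return PairedTResult(
        mean_difference=mean, t=t, p=p, df=n - 1,
        significant=p < alpha, flags=tuple(flags),
    )


def evaluate_batch(
    preds,
    truths,
    names=None,
    originals=None,
    enhanced=None,
    groups=None,
) -> pd.DataFrame:
    """Per-image metric table with a mean and (sample) std summary.

    ``originals``/``enhanced`` (optional, paired lists of grayscale images)
    add a PSNR column measuring enhancement fidelity.  ``groups`` (optional
    labels, e.g. normal/abnormal) add groupwise mean rows and a macro
    average.  Rows ``mean`` and ``std`` close the table.
    """
    preds = list(preds)
    truths = list(truths)
    if len(preds) != len(truths) or not preds:
        raise ValueError("preds and truths must be non-empty lists of equal length")
    if originals is not None or enhanced is not None:
        if originals is None or enhanced is None or len(originals) != len(preds) or len(enhanced) != len(preds):
            raise ValueError("originals and enhanced must both be given, one per image")
    if names is None:
        names = [f"image_{i:03d}" for i in range(len(preds))]
    rows = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        rep = metrics(confusion(p, t), image=str(names[i]))
        row = {
            "image": rep.image,
            "precision": rep.precision,
            "recall": rep.recall,
            "f1": rep.f1,
            "accuracy": rep.accuracy,
            "flags": ";".join(rep.flags),
        }
        if originals is not None:
            row["psnr"] = psnr(originals[i], enhanced[i])
        if groups is not None:
            row["group"] = groups[i]
        rows.append(row)
    df = pd.DataFrame(rows)
    value_cols = [c for c in df.columns if c not in ("image", "flags", "group")]

    summary_rows = []
    if groups is not None:
        group_means = df.groupby("group")[value_cols].mean()
        for g, vals in group_means.iterrows():
            summary_rows.append({"image": f"mean[{g}]", **vals.to_dict()})
        summary_rows.append({"image": "macro_average", **group_means.mean().to_dict()})
    summary_rows.append({"image": "mean", **df[value_cols].mean().to_dict()})
    summary_rows.append({"image": "std", **df[value_cols].std(ddof=1).to_dict()})
    return pd.concat([df, pd.DataFrame(summary_rows)], ignore_index=True)
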