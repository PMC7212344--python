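"""Evaluation of QA predictions: one-vs-rest classification metrics.

Quality-level predictions are scored per class in one-vs-rest fashion:
class ``g`` is the positive class, all others negative, giving TP / FP /
TN / FN counts from which balanced accuracy ``BA = (sensitivity +
specificity) / 2``, the F score ``2TP / (2TP + FN + FP)`` and the ROC AUC
(rank statistic, ties counted half) are computed.  Direct DSC-value
predictions are scored by the mean absolute error over all pooled test
slices, together with the spread of absolute errors, the Pearson
correlation, and the fraction of predictions within fixed error margins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import qa

__all__ = [
    "ovr_confusion",
    "balanced_accuracy",
    "f_score",
    "auc_ovr",
    "mae",
    "misclassification_histogram",
    "levels_report",
    "dsc_value_report",
]


def ovr_confusion(
    y_true: Sequence[int], y_pred: Sequence[int],
    classes: tuple[int, ...] = (qa.GOOD, qa.MEDIUM, qa.BAD),
) -> dict[int, dict[str, int]]:
    """One-vs-rest confusion counts per class.

    For each class g: TP = #(true=g and pred=g), FN = #(true=g, pred!=g),
    FP = #(true!=g, pred=g), TN = #(true!=g, pred!=g).
    """
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError(f"label arrays must be 1D and equal length, got {yt.shape} vs {yp.shape}")
    known = np.isin(yt, classes) & np.isin(yp, classes)
    if not known.all():
        bad = np.unique(np.r_[yt[~np.isin(yt, classes)], yp[~np.isin(yp, classes)]])
        raise ValueError(f"unknown class labels {bad.tolist()}; expected {classes}")
    out = {}
    for g in classes:
        tp = int(((yt == g) & (yp == g)).sum())
        fn = int(((yt == g) & (yp != g)).sum())
        fp = int(((yt != g) & (yp == g)).sum())
        tn = int(((yt != g) & (yp != g)).sum())
        out[g] = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
    return out


def balanced_accuracy(counts: Mapping[str, int]) -> float:
    """BA = (TP/(TP+FN) + TN/(TN+FP)) / 2 for one class's counts."""
    tp, fn, tn, fp = counts["TP"], counts["FN"], counts["TN"], counts["FP"]
    if tp + fn == 0:
        raise ValueError("no positive instances: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negative instances: specificity undefined")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def f_score(counts: Mapping[str, int]) -> float:
    """F = 2TP / (2TP + FN + FP) for one class's counts."""
    tp, fn, fp = counts["TP"], counts["FN"], counts["FP"]
    denom = 2 * tp + fn + fp
    if denom == 0:
        raise ValueError("F score undefined: no positives in truth or prediction")
    return 2 * tp / denom


def auc_ovr(
    y_true: Sequence[int], scores: np.ndarray,
    classes: tuple[int, ...] = (qa.GOOD, qa.MEDIUM, qa.BAD),
) -> dict[int, float]:
    """Per-class one-vs-rest ROC AUC from softmax scores.

    Uses the Mann-Whitney rank statistic (equivalent to trapezoidal
    integration of the ROC curve), with tied scores contributing 1/2.
    Classes absent from ``y_true`` (or covering all of it) have an
    undefined ROC and are reported as ``nan``.
    """
    yt = np.asarray(y_true)
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim != 2 or s.shape[0] != len(yt):
        raise ValueError(f"scores must be (n, n_classes), got {s.shape} for {len(yt)} labels")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    from scipy.stats import rankdata

    out = {}
    for k, g in enumerate(classes):
        pos = yt == g
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            out[g] = float("nan")
            continue
        ranks = rankdata(s[:, k])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        out[g] = float(u / (n_pos * n_neg))
    return out


def mae(dsc_pred: Sequence[float], dsc_true: Sequence[float]) -> tuple[float, float]:
    """Mean absolute error and SD of absolute errors over pooled slices."""
    p = np.asarray(dsc_pred, dtype=np.float64)
    t = np.asarray(dsc_true, dtype=np.float64)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    for name, a in (("dsc_pred", p), ("dsc_true", t)):
        if a.min() < 0 or a.max() > 1:
            raise ValueError(f"{name} values must lie in [0, 1]")
    err = np.abs(p - t)
    return float(err.mean()), float(err.std())


def misclassification_histogram(
    dsc_true: Sequence[float],
    y_true: Sequence[int],
    y_pred: Sequence[int],
    bin_width: float = 0.05,
) -> dict[int, dict]:
    """True-DSC histograms of the misclassified slices, per predicted class.

    For each predicted class, the histogram of the true DSC restricted to
    slices whose predicted class differs from the true one.  Bins are
    half-open ``[lo, lo + width)`` with the final bin closed at 1.
    """
    d = np.asarray(dsc_true, dtype=np.float64)
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if not (len(d) == len(yt) == len(yp)):
        raise ValueError("inputs must be aligned")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    out = {}
    for g in (qa.GOOD, qa.MEDIUM, qa.BAD):
        sel = (yp == g) & (yt != yp)
        counts, _ = np.histogram(d[sel], bins=edges)
        out[g] = {"edges": edges.tolist(), "counts": counts.astype(int).tolist()}
    return out


def levels_report(
    y_true: Sequence[int], y_pred: Sequence[int], scores: np.ndarray | None = None,
) -> dict:
    """Per-class BA / F / AUC summary for quality-level predictions."""
    counts = ovr_confusion(y_true, y_pred)
    report: dict = {"n": int(len(np.asarray(y_true))), "per_class": {}}
    aucs = auc_ovr(y_true, scores) if scores is not None else None
    for g, name in qa.QUALITY_NAMES.items():
        entry = {"counts": counts[g]}
        try:
            entry["ba"] = balanced_accuracy(counts[g])
        except ValueError:
            entry["ba"] = float("nan")
        try:
            entry["f_score"] = f_score(counts[g])
        except ValueError:
            entry["f_score"] = float("nan")
        if aucs is not None:
            entry["auc"] = aucs[g]
        report["per_class"][name] = entry
    report["accuracy"] = float((np.asarray(y_true) == np.asarray(y_pred)).mean())
    return report


def dsc_value_report(
    dsc_pred: Sequence[float], dsc_true: Sequence[float],
    thresholds: Sequence[float] = (0.03, 0.05, 0.10),
) -> dict:
    """MAE / correlation / within-margin summary for direct DSC prediction."""
    p = np.asarray(dsc_pred, dtype=np.float64)
    t = np.asarray(dsc_true, dtype=np.float64)
    m, sd = mae(p, t)
    err = p - t
    report = {
        "n": int(p.size),
        "mae": m,
        "abs_error_sd": sd,
        "mean_signed_error": float(err.mean()),
        "within": {f"{thr:.2f}": float((np.abs(err) <= thr + 1e-12).mean())
                   for thr in thresholds},
    }
    if p.size > 1 and p.std() > 0 and t.std() > 0:
        report["pearson_r"] = float(np.corrcoef(p, t)[0, 1])
    else:
        report["pearson_r"] = float("nan")
    return report


# ----------------------------------------------------------------- plots ---


def plot_misclassification_histograms(hist: dict[int, dict], path) -> None:
    """Render per-predicted-class misclassified-DSC histograms to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=True)
    for ax, (g, name) in zip(axes, qa.QUALITY_NAMES.items()):
        h = hist[g]
        edges = np.asarray(h["edges"])
        ax.bar(edges[:-1], h["counts"], width=np.diff(edges), align="edge",
               edgecolor="k", linewidth=0.3)
        ax.set_title(f"misclassified as {name}")
        ax.set_xlabel("true DSC")
    axes[0].set_ylabel("slices")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_dsc_scatter(dsc_pred, dsc_true, path, margin: float = 0.10) -> None:
    """Predicted-vs-true DSC scatter with a +/- margin band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    ax.scatter(dsc_true, dsc_pred, s=8, alpha=0.5)
    line = np.linspace(0, 1, 2)
    ax.plot(line, line, "k-", lw=0.8)
    ax.plot(line, np.clip(line + margin, 0, 1), "k--", lw=0.8)
    ax.plot(line, np.clip(line - margin, 0, 1), "k--", lw=0.8)
    ax.set_xlabel("true DSC")
    ax.set_ylabel("predicted DSC")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
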