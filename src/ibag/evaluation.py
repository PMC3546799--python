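"""Metrics for model comparison and survival prediction assessment."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["RocResult", "roc_auc", "c_index", "empirical_fdp", "mean_roc"]


@dataclass(frozen=True)
class RocResult:
    """One ROC sweep: thresholds, operating points and trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> RocResult:
    """ROC curve and AUC for a continuous score against 0/1 labels.

    The threshold sweep visits every distinct score; the trapezoidal
    AUC equals the Mann-Whitney concordance statistic (ties counted
    half).
    """
    y = np.asarray(truth, dtype=float)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise ValueError("need at least one positive and one negative label")
    fpr, tpr, thresholds = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def c_index(predicted: np.ndarray, t: np.ndarray, delta: np.ndarray | None = None) -> float:
    """Harrell's concordance index for right-censored survival data.

    A pair (i, j) with ``t_i > t_j`` is comparable when the smaller
    time is an observed event; it scores 1 when the prediction orders
    the pair the same way (``predicted_i > predicted_j``, predictions
    on a longer-survival-is-larger scale), 0.5 on a prediction tie.
    """
    pred = np.asarray(predicted, dtype=float)
    t = np.asarray(t, dtype=float)
    d = np.ones_like(t) if delta is None else np.asarray(delta, dtype=float)
    if pred.shape != t.shape or d.shape != t.shape:
        raise ValueError("predictions, times and events must align")
    # comparable[i, j]: t_i > t_j and subject j had the event
    comparable = (t[:, None] > t[None, :]) & (d[None, :] == 1.0)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (all times tied or all censored)")
    agree = pred[:, None] > pred[None, :]
    tied = pred[:, None] == pred[None, :]
    score = (agree & comparable).sum() + 0.5 * (tied & comparable).sum()
    return float(score / n_comp)


def empirical_fdp(selected: Iterable[str], true_genes: Iterable[str]) -> float:
    """Realized false-discovery proportion of a selection.

    ``|selected \\ truth| / max(|selected|, 1)`` — an empty selection
    scores 0 by the max guard.
    """
    sel = set(selected)
    truth = set(true_genes)
    return len(sel - truth) / max(len(sel), 1)


def mean_roc(curves: Sequence[RocResult], grid: np.ndarray | None = None) -> RocResult:
    """Vertical (pointwise-in-FPR) average of ROC curves across replicates."""
    if not curves:
        raise ValueError("need at least one curve")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    tprs = np.vstack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    tpr = tprs.mean(axis=0)
    return RocResult(thresholds=np.array([]), fpr=grid, tpr=tpr, auc=float(np.trapezoid(tpr, grid)))
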