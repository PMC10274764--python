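"""Balanced ROC curves for the trinomial matched/unmatched/ambiguous classifier.

Positives are truth-unmatched instances, negatives truth-matched.  Because
the classifier may also abstain ("ambiguous"), the usual TPR/FPR pair is
replaced by balanced rates

    BTPR = (TPR + TNR) / 2        BFPR = (FPR + FNR) / 2

where ambiguous calls count toward no numerator — they deflate correct and
incorrect rates alike.  Varying the z-score of the bin classifier traces a
curve; AUC is the trapezoid area after sorting by BFPR and appending the
(0,0) and (1,1) anchors (the balanced curve need not reach them on its
own).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_Z_GRID = np.arange(0.0, 5.0001, 0.05)


@dataclass(frozen=True)
class BalancedRocCurve:
    """Points (z, BTPR, BFPR) and the anchored trapezoid AUC."""

    z: np.ndarray
    btpr: np.ndarray
    bfpr: np.ndarray
    auc: float


def balanced_rates(
    truth: Sequence[str], predicted: Sequence[str]
) -> tuple[float, float]:
    """(BTPR, BFPR) for one operating point.

    ``truth`` entries are "matched"/"unmatched"; ``predicted`` may also be
    "ambiguous".  Requires at least one instance of each truth class.
    """
    if len(truth) != len(predicted):
        raise ValueError("truth and predictions differ in length")
    t = np.asarray(truth)
    p = np.asarray(predicted)
    pos = t == "unmatched"
    neg = t == "matched"
    if not pos.any() or not neg.any():
        raise ValueError("need both truth classes to compute balanced rates")
    tpr = float((p[pos] == "unmatched").mean())
    fnr_as_matched = float((p[pos] == "matched").mean())
    tnr = float((p[neg] == "matched").mean())
    fpr = float((p[neg] == "unmatched").mean())
    btpr = 0.5 * (tpr + tnr)
    bfpr = 0.5 * (fpr + fnr_as_matched)
    return btpr, bfpr


def balanced_roc(
    truth: Sequence[str],
    classify_at: "callable",
    z_grid: np.ndarray = DEFAULT_Z_GRID,
) -> BalancedRocCurve:
    """Trace the balanced ROC by sweeping the classification z-score.

    ``classify_at(z)`` must return the predicted labels at threshold z.
    """
    points = []
    for z in z_grid:
        btpr, bfpr = balanced_rates(truth, classify_at(float(z)))
        points.append((float(z), btpr, bfpr))
    zs = np.array([p[0] for p in points])
    btpr = np.array([p[1] for p in points])
    bfpr = np.array([p[2] for p in points])
    auc = anchored_auc(btpr, bfpr)
    return BalancedRocCurve(z=zs, btpr=btpr, bfpr=bfpr, auc=auc)


def anchored_auc(btpr: np.ndarray, bfpr: np.ndarray) -> float:
    """Trapezoid AUC over points sorted by BFPR with (0,0),(1,1) anchors."""
    x = np.concatenate([[0.0], np.asarray(bfpr, dtype=float), [1.0]])
    y = np.concatenate([[0.0], np.asarray(btpr, dtype=float), [1.0]])
    order = np.lexsort((y, x))
    return float(np.trapezoid(y[order], x[order]))
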