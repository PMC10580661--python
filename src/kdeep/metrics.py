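"""Evaluation metrics: auROC and auPRC (average precision).

auROC is the probability that a random positive outranks a random negative
(ties counting one half); auPRC is step-wise average precision — the sum
over score-descending thresholds of recall increment times precision, with
no trapezoidal interpolation.  Both delegate to scikit-learn; the test suite
checks them against brute-force pairwise-counting and threshold-enumeration
oracles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores ({scores.shape}) and labels ({labels.shape}) differ in length"
        )
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return scores, labels.astype(int)


def auroc(scores, labels) -> float:
    """Area under the ROC curve; errors explicitly on single-class input."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError(
            "auROC undefined: input contains a single class "
            f"({n_pos} positives out of {len(labels)})"
        )
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Average precision; requires at least one positive."""
    scores, labels = _validate(scores, labels)
    if labels.sum() == 0:
        raise ValueError("auPRC undefined: no positive labels")
    return float(average_precision_score(labels, scores))


def per_target_report(
    score_matrix: np.ndarray, label_matrix: np.ndarray
) -> pd.DataFrame:
    """Per-target auROC/auPRC table with macro averages.

    Targets whose labels contain a single class are flagged (``degenerate``)
    and excluded from the macro averages.  The returned frame has one row per
    target plus a final ``macro`` row.
    """
    scores = np.atleast_2d(np.asarray(score_matrix, dtype=float))
    labels = np.atleast_2d(np.asarray(label_matrix))
    if scores.shape != labels.shape:
        raise ValueError(
            f"score matrix {scores.shape} and label matrix {labels.shape} differ"
        )
    rows = []
    for t in range(scores.shape[1]):
        col_labels = labels[:, t]
        degenerate = col_labels.min() == col_labels.max()
        if degenerate:
            warnings.warn(
                f"target {t} has a single label class; excluded from macro averages",
                stacklevel=2,
            )
            rows.append(dict(target=t, auroc=np.nan, auprc=np.nan, degenerate=True))
        else:
            rows.append(
                dict(
                    target=t,
                    auroc=auroc(scores[:, t], col_labels),
                    auprc=auprc(scores[:, t], col_labels),
                    degenerate=False,
                )
            )
    report = pd.DataFrame(rows)
    valid = report[~report["degenerate"]]
    macro = pd.DataFrame(
        [
            dict(
                target="macro",
                auroc=valid["auroc"].mean(),
                auprc=valid["auprc"].mean(),
                degenerate=False,
            )
        ]
    )
    return pd.concat([report, macro], ignore_index=True)
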