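"""ROC curves and AUC for the MS-discriminating classifiers.

Scores are oriented a priori: a higher AMR or coNCS predicts MS.  Curves
place one threshold at every distinct score value (ties collapse to a single
point); infinite sentinel scores are permitted and rank above all finite
values.  The trapezoidal AUC of the curve equals the Mann-Whitney pair
fraction (ties counted 1/2), which doubles as the package's independent
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class ROCResult:
    contrast: str
    score_name: str
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if np.isnan(scores).any():
        raise ValueError("scores must not contain NaN")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


def roc_curve(scores, labels, contrast: str = "",
              score_name: str = "") -> ROCResult:
    """ROC curve with a point per distinct score value, from (0,0) to (1,1)."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.r_[s[:-1] != s[1:], True]   # last index of each tied block
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(contrast=contrast, score_name=score_name, fpr=fpr,
                     tpr=tpr, thresholds=thresholds, auc=auc,
                     n_pos=n_pos, n_neg=n_neg)


def auc_mann_whitney(scores, labels) -> float:
    """Fraction of (positive, negative) pairs ranked concordantly, ties 1/2."""
    scores, labels = _validate(scores, labels)
    ranks = rankdata(scores)           # average ranks; inf handled naturally
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_table(results: list[ROCResult]) -> pd.DataFrame:
    """Summary frame: contrast, score, auc, class sizes."""
    return pd.DataFrame([{
        "contrast": r.contrast, "score": r.score_name, "auc": r.auc,
        "n_pos": r.n_pos, "n_neg": r.n_neg} for r in results])
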