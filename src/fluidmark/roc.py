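"""ROC/AUC evaluation of a marker's two-class discrimination.

The AUC is the probability that a randomly chosen positive (tumor) scores
above a randomly chosen negative (normal), with ties given half credit:

    AUC = P(s_pos > s_neg) + 0.5 * P(s_pos = s_neg)

computed from the midrank (Mann–Whitney) statistic. Discrimination tiers
follow the standard convention: AUC >= 0.9 outstanding, [0.8, 0.9)
excellent, [0.7, 0.8) acceptable, below 0.7 none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["RocResult", "compute_roc", "classify_tier", "auc_midrank"]

TIER_BOUNDS = {"outstanding": 0.9, "excellent": 0.8, "acceptable": 0.7}


@dataclass(frozen=True)
class RocResult:
    auc: float
    curve: list[tuple[float, float]]  # (fpr, tpr), (0,0) .. (1,1)
    n_pos: int
    n_neg: int
    tier: str


def auc_midrank(scores, labels) -> float:
    """AUC via the midrank statistic: (R_pos - n_pos(n_pos+1)/2) / (n_pos n_neg)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    ranks = rankdata(s)  # midranks for ties
    r_pos = ranks[y].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_roc(scores, labels) -> RocResult:
    """ROC curve (threshold sweep over unique scores) and midrank AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    auc = auc_midrank(s, y)
    n_pos, n_neg = int(y.sum()), int((~y).sum())

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep one operating point per unique threshold
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    curve = list(zip(fpr.tolist(), tpr.tolist()))
    return RocResult(auc=auc, curve=curve, n_pos=n_pos, n_neg=n_neg,
                     tier=classify_tier(auc))


def classify_tier(auc: float) -> str:
    """Discrimination tier for an AUC in [0, 1]."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"auc outside [0, 1]: {auc}")
    if auc >= TIER_BOUNDS["outstanding"]:
        return "outstanding"
    if auc >= TIER_BOUNDS["excellent"]:
        return "excellent"
    if auc >= TIER_BOUNDS["acceptable"]:
        return "acceptable"
    return "none"
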