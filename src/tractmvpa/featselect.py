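"""Univariate F-score voxel ranking and top-fraction retention.

The score for voxel v with class means xbar+, xbar-, overall mean xbar
and class sample variances s+^2, s-^2 (n-1 denominators) is

    F(v) = [(xbar+ - xbar)^2 + (xbar- - xbar)^2] / (s+^2 + s-^2),

the two-class separability criterion commonly used to pre-rank features
for SVM training.  Selection is always computed on the training fold
only; see :mod:`tractmvpa.evaluate` for the leave-one-out plumbing.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

__all__ = ["SelectionResult", "fscore", "select_top_fraction"]


@dataclass(frozen=True)
class SelectionResult:
    scores: np.ndarray
    retained: np.ndarray        # voxel positions, highest score first
    fraction: float


def fscore(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-voxel two-class F-scores.

    A voxel where both classes are constant scores 0 when the means also
    agree, and +inf when they differ (perfectly separating voxel).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos = X[y > 0]
    neg = X[y <= 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 subjects per class")
    mean = X.mean(axis=0)
    num = (pos.mean(axis=0) - mean) ** 2 + (neg.mean(axis=0) - mean) ** 2
    den = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    out = np.empty_like(num)
    zero_den = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero_den, np.where(num == 0, 0.0, np.inf), num / np.where(zero_den, 1.0, den))
    return out


def select_top_fraction(scores: np.ndarray, fraction: float) -> SelectionResult:
    """Retain the ceil(fraction * V) highest-scoring voxels.

    Ties are broken toward the lower voxel index so the retained set is
    deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = ceil(fraction * scores.size)
    order = np.argsort(-scores, kind="stable")  # stable: lower index wins ties
    return SelectionResult(scores=scores, retained=order[:k], fraction=fraction)
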