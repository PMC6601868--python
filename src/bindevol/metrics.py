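"""Shared statistical primitives with exact contracts.

Pearson correlation with a Student-t p-value evaluated in log space (so that
extreme significance levels, e.g. ~1e-131 at n=2754, remain representable),
rank-sum AUROC with the ties-count-half convention, and balanced accuracy
from a confusion matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "ConfusionSummary",
    "pearson_with_pvalue",
    "auroc",
    "balanced_accuracy",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson coefficient with its two-sided t-based p-value.

    p is derived from t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of
    freedom, evaluated through the log tail of the t distribution.
    """

    r: float
    n: int
    p: float

    def __iter__(self):
        return iter((self.r, self.p))


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts plus the derived rates used throughout."""

    tn: int
    fn: int
    tp: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("tn", "fn", "tp", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name}")

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise ValueError("no positive samples: sensitivity undefined")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise ValueError("no negative samples: specificity undefined")
        return self.tn / (self.tn + self.fp)

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


def pearson_with_pvalue(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided Student-t p-value.

    The p-value uses the transform t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees
    of freedom and is computed via ``t.logsf`` so that values far below the
    double-precision underflow of the naive density survive.

    Raises
    ------
    ValueError
        If fewer than 3 samples, or either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("undefined correlation: constant input")
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    p = _t_pvalue(r, n)
    return CorrelationResult(r=r, n=n, p=p)


def _t_pvalue(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    df = n - 2
    t = abs(r) * math.sqrt(df / (1.0 - r * r))
    logp = math.log(2.0) + stats.t.logsf(t, df)
    return float(math.exp(min(logp, 0.0)))


def pvalue_for_r(r: float, n: int) -> float:
    """p-value of a given Pearson r at sample size n (t transform)."""
    if n < 3:
        raise ValueError("need n >= 3")
    return _t_pvalue(r, n)


def auroc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative.

    Rank-sum (Mann-Whitney) formulation; tied scores count one half.

    Raises
    ------
    ValueError
        If either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # average rank for ties => half-credit
    rank_sum = float(ranks[labels].sum())
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def balanced_accuracy(cs: ConfusionSummary) -> float:
    """(sensitivity + specificity) / 2 of a confusion summary."""
    return cs.balanced_accuracy
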