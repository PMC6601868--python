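"""Shared-accessibility analysis of correlated binding changes.

Two TFs' binding changes at the same time point are often correlated; part
of that correlation can be carried by a common change in chromatin
accessibility. The statistic here regresses each TF's measured dChIP on an
accessibility-based prediction (reusing the out-of-fold predictions of
:mod:`bindevol.deltapred` — no refit) and correlates the residuals. It is
related to, but deliberately not called, a partial correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .deltapred import DeltaPrediction
from .metrics import pearson_with_pvalue
from .scoring import delta_table
from .simulate import SyntheticCohort, condition_tf, condition_tp

__all__ = ["CodivergenceResult", "residual_correlation", "codivergence_screen"]


@dataclass(frozen=True)
class CodivergenceResult:
    """Raw vs accessibility-residual correlation of two TFs' dChIP columns."""

    tf1: str
    tf2: str
    tp: int
    raw_r: float
    residual_r: float

    @property
    def drop(self) -> float:
        return self.raw_r - self.residual_r


def _find_prediction(
    predictions: list[DeltaPrediction], condition: str
) -> DeltaPrediction:
    for p in predictions:
        if p.condition == condition and p.variant in ("acc_matched", "acc_all_tp"):
            return p
    raise ValueError(f"no accessibility-based prediction for {condition}")


def residual_correlation(
    cohort: SyntheticCohort,
    predictions: list[DeltaPrediction],
    tf1: str,
    tf2: str,
    tp: int,
) -> CodivergenceResult:
    """Correlation of the two TFs' dChIP after removing the accessibility part.

    The residual for each TF is measured dChIP minus the out-of-fold
    accessibility-based prediction for that TF's condition at the time
    point. If the accessibility predictions are constant the residual
    correlation equals the raw correlation exactly.
    """
    cond1, cond2 = f"{tf1}:TP{tp}", f"{tf2}:TP{tp}"
    dchip = delta_table(cohort.chip_mel, cohort.chip_vir)
    y1, y2 = dchip.column(cond1), dchip.column(cond2)
    raw_r = pearson_with_pvalue(y1, y2).r
    p1 = _find_prediction(predictions, cond1)
    p2 = _find_prediction(predictions, cond2)
    res1 = y1 - p1.predicted
    res2 = y2 - p2.predicted
    residual_r = pearson_with_pvalue(res1, res2).r
    return CodivergenceResult(
        tf1=tf1, tf2=tf2, tp=tp, raw_r=raw_r, residual_r=residual_r
    )


def codivergence_screen(
    cohort: SyntheticCohort,
    predictions: list[DeltaPrediction],
    min_raw_r: float = 0.2,
    drop_threshold: float = 0.04,
) -> list[tuple[CodivergenceResult, bool]]:
    """All same-time-point TF pairs with strongly correlated binding changes.

    Returns each pair with raw correlation above ``min_raw_r`` together
    with a flag marking whether removing the accessibility component drops
    the correlation by at least ``drop_threshold``. Symmetric in TF order.
    """
    conditions = list(cohort.chip_mel.columns)
    by_tp: dict[int, list[str]] = {}
    for cond in conditions:
        by_tp.setdefault(condition_tp(cond), []).append(condition_tf(cond))
    out: list[tuple[CodivergenceResult, bool]] = []
    for tp, tfs in sorted(by_tp.items()):
        for tf1, tf2 in combinations(sorted(set(tfs)), 2):
            try:
                res = residual_correlation(cohort, predictions, tf1, tf2, tp)
            except ValueError:
                continue  # no accessibility prediction at this time point
            if res.raw_r > min_raw_r:
                out.append((res, res.drop >= drop_threshold))
    return out
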