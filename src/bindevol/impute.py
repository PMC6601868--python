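"""Imputed ortholog ChIP profiles and activity-change agreement.

The ortholog's 14-condition ChIP profile is imputed as the reference
profile minus the predicted interspecies change (clipped to [0,1] so it is
a valid classifier input). Activity change estimated from measured
profiles (dA_C = A_C[mel] - A_C[vir]) is compared against the estimate
from imputed profiles (dA_C-hat) by Pearson correlation and by the AUROC
of separating the most-changed from the most-conserved pairs, with a
permuted-dChIP control as the null baseline: whole rows of the measured
dChIP matrix are shuffled across enhancers, keeping each enhancer's
14 conditions together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .activity import ActivityModel
from .deltapred import DeltaPrediction
from .metrics import auroc, pearson_with_pvalue
from .scoring import delta_table
from .simulate import SyntheticCohort

__all__ = [
    "AgreementResult",
    "impute_ortholog_chip",
    "select_assessment_set",
    "assess_agreement",
    "permuted_control",
]


@dataclass
class AgreementResult:
    """Agreement between measured- and imputed-profile activity changes."""

    cls: str
    high_ids: list[str]
    low_ids: list[str]
    dA: np.ndarray  # over selected ids, high then low
    dA_hat: np.ndarray
    r: float
    auroc: float
    control_r: float
    control_auroc: float

    @property
    def n(self) -> int:
        return len(self.high_ids) + len(self.low_ids)


def impute_ortholog_chip(
    mel_profile: np.ndarray, predicted_dchip: np.ndarray
) -> np.ndarray:
    """Imputed ortholog profile: reference minus predicted change, clipped.

    Since dChIP = mel - vir, the imputed vir profile is mel - predicted
    dChIP; clipping to [0,1] keeps it on the normalized score scale.
    """
    mel_profile = np.asarray(mel_profile, dtype=float)
    predicted_dchip = np.asarray(predicted_dchip, dtype=float)
    if mel_profile.shape != predicted_dchip.shape:
        raise ValueError(
            f"profile shape {mel_profile.shape} != "
            f"prediction shape {predicted_dchip.shape}"
        )
    return np.clip(mel_profile - predicted_dchip, 0.0, 1.0)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_assessment_set(
    ids: list[str],
    ac_scores: np.ndarray,
    da: np.ndarray,
    top_pct: float = 20.0,
    extreme_pct: float = 10.0,
) -> tuple[list[str], list[str]]:
    """Ids with the most and least predicted activity change.

    First restrict to the floor(n * top_pct/100) enhancers with the
    highest reference-species confidence A_C; within that set take the
    round(m * extreme_pct/100) highest-dA ids (changed) and as many
    lowest-dA ids (conserved). Ties break by stable input order.
    """
    if not (0.0 < top_pct <= 100.0) or not (0.0 < extreme_pct <= 50.0):
        raise ValueError("top_pct in (0,100], extreme_pct in (0,50] required")
    ids = list(ids)
    ac_scores = np.asarray(ac_scores, dtype=float)
    da = np.asarray(da, dtype=float)
    n = len(ids)
    m = int(math.floor(n * top_pct / 100.0))
    top = np.argsort(ac_scores, kind="stable")[::-1][:m]
    k = _round_half_up(m * extreme_pct / 100.0)
    if k < 10:
        raise ValueError(f"only {k} ids per side; need at least 10")
    order = top[np.argsort(da[top], kind="stable")]
    low = order[:k]
    high = order[-k:][::-1]
    return [ids[i] for i in high], [ids[i] for i in low]


def _predicted_dchip_matrix(
    predictions: list[DeltaPrediction],
    variant: str,
    conditions: list[str],
    ids: list[str],
) -> np.ndarray:
    by_cond = {p.condition: p for p in predictions if p.variant == variant}
    missing = [c for c in conditions if c not in by_cond]
    if missing:
        raise ValueError(f"no {variant!r} predictions for conditions {missing}")
    mat = np.empty((len(ids), len(conditions)))
    for j, cond in enumerate(conditions):
        p = by_cond[cond]
        if p.ids != ids:
            index = {e: i for i, e in enumerate(p.ids)}
            mat[:, j] = p.predicted[[index[e] for e in ids]]
        else:
            mat[:, j] = p.predicted
    return mat


def assess_agreement(
    cohort: SyntheticCohort,
    predictions: list[DeltaPrediction],
    models: dict[str, ActivityModel],
    cls: str,
    variant: str = "combined",
    top_pct: float = 20.0,
    extreme_pct: float = 10.0,
    seed: int = 0,
) -> AgreementResult:
    """Compare measured- vs imputed-profile activity change for one class.

    The same reference-species-trained classifier scores both species'
    profiles. The control value imputes from a row-permuted measured
    dChIP matrix with the given seed.
    """
    model = models[cls]
    ids = cohort.ids
    conditions = list(cohort.chip_mel.columns)
    mel = cohort.chip_mel.values
    vir = cohort.chip_vir.values

    a_mel = model.predict_confidence(mel)
    a_vir = model.predict_confidence(vir)
    dA_all = a_mel - a_vir

    pred_mat = _predicted_dchip_matrix(predictions, variant, conditions, ids)
    imputed = impute_ortholog_chip(mel, pred_mat)
    dA_hat_all = a_mel - model.predict_confidence(imputed)

    high, low = select_assessment_set(
        ids, a_mel, dA_all, top_pct=top_pct, extreme_pct=extreme_pct
    )
    index = {e: i for i, e in enumerate(ids)}
    sel = [index[e] for e in high] + [index[e] for e in low]
    labels = np.concatenate(
        [np.ones(len(high), bool), np.zeros(len(low), bool)]
    )
    dA = dA_all[sel]
    dA_hat = dA_hat_all[sel]
    r = pearson_with_pvalue(dA, dA_hat).r
    roc = auroc(dA_hat, labels)

    ctrl_r, ctrl_roc = permuted_control(
        cohort, model, a_mel, dA, sel, labels, seed=seed
    )
    return AgreementResult(
        cls=cls,
        high_ids=high,
        low_ids=low,
        dA=dA,
        dA_hat=dA_hat,
        r=r,
        auroc=roc,
        control_r=ctrl_r,
        control_auroc=ctrl_roc,
    )


def permuted_control(
    cohort: SyntheticCohort,
    model: ActivityModel,
    a_mel: np.ndarray | None = None,
    dA: np.ndarray | None = None,
    sel: list[int] | None = None,
    labels: np.ndarray | None = None,
    seed: int = 0,
    top_pct: float = 20.0,
    extreme_pct: float = 10.0,
    permutation: np.ndarray | None = None,
) -> tuple[float, float]:
    """Agreement when imputing from a row-permuted measured dChIP matrix.

    Whole enhancers (14-dimensional dChIP rows) are shuffled, preserving
    each column's marginal distribution exactly. With the identity
    permutation this reduces to imputing from the true measured changes.
    Deterministic given seed.
    """
    ids = cohort.ids
    mel = cohort.chip_mel.values
    if a_mel is None:
        a_mel = model.predict_confidence(mel)
    if dA is None or sel is None or labels is None:
        dA_all = a_mel - model.predict_confidence(cohort.chip_vir.values)
        high, low = select_assessment_set(
            ids, a_mel, dA_all, top_pct=top_pct, extreme_pct=extreme_pct
        )
        index = {e: i for i, e in enumerate(ids)}
        sel = [index[e] for e in high] + [index[e] for e in low]
        labels = np.concatenate(
            [np.ones(len(high), bool), np.zeros(len(low), bool)]
        )
        dA = dA_all[sel]

    dchip = delta_table(cohort.chip_mel, cohort.chip_vir).values
    if permutation is None:
        rng = np.random.default_rng(seed)
        permutation = rng.permutation(len(ids))
    permuted = dchip[permutation]
    imputed = impute_ortholog_chip(mel, permuted)
    dA_hat = a_mel - model.predict_confidence(imputed)
    r = pearson_with_pvalue(dA, dA_hat[sel]).r
    roc = auroc(dA_hat[sel], labels)
    return r, roc
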