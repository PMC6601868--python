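"""Cross-validated regression of interspecies binding change.

For each TF:time-point condition, an epsilon-insensitive support-vector
regression (RBF kernel, cost 1, epsilon 0.1, kernel width 1/n_features,
features standardized within each training fold) predicts the normalized
ChIP-score change dChIP = ChIP_mel - ChIP_vir from one of four feature
variants:

``acc_matched``  (Acc_mel[tp], dAcc[tp]) at the condition's time point
``acc_all_tp``   Acc_mel and dAcc at all three assayed time points
``motif``        (STAP_mel[cond], dSTAP[cond])
``combined``     motif features plus acc_all_tp features (8 features)

Evaluation is by Pearson correlation of out-of-fold predictions (both the
pooled correlation and the mean of per-fold correlations are computed) and
by the AUROC of separating the top from the bottom decile of measured
change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .metrics import CorrelationResult, auroc, pearson_with_pvalue
from .scoring import ScoreTable, delta_table
from .simulate import (
    ACC_TIME_POINTS,
    SyntheticCohort,
    condition_tf,
    condition_tp,
)
from .stap import StapModel, StapTrainingSet, fit_gamma, stap_score_table

__all__ = [
    "VARIANTS",
    "DeltaFeatures",
    "DeltaPrediction",
    "build_features",
    "fit_predict_cv",
    "evaluate_pcc",
    "evaluate_decile_auroc",
    "run_condition_matrix",
    "train_stap_models",
    "compute_stap_tables",
]

VARIANTS = ("acc_matched", "acc_all_tp", "motif", "combined")


@dataclass
class DeltaFeatures:
    """Feature matrix for one condition under one variant."""

    variant: str
    condition: str
    ids: list[str]
    names: list[str]
    matrix: np.ndarray


@dataclass
class DeltaPrediction:
    """Out-of-fold dChIP predictions for one condition/variant with scores."""

    condition: str
    variant: str
    ids: list[str]
    predicted: np.ndarray
    measured: np.ndarray
    fold: np.ndarray
    pcc: CorrelationResult  # pooled out-of-fold correlation
    pcc_fold_mean: float  # mean of per-fold correlations
    auroc_decile: float


def _acc_features(cohort: SyntheticCohort, tps) -> tuple[list[str], np.ndarray]:
    dacc = delta_table(cohort.acc_mel, cohort.acc_vir)
    names, cols = [], []
    for t in tps:
        col = f"Acc:TP{t}"
        names += [f"AccMel:TP{t}", f"dAcc:TP{t}"]
        cols += [cohort.acc_mel.column(col), dacc.column(col)]
    return names, np.column_stack(cols)


def build_features(
    cohort: SyntheticCohort,
    variant: str,
    condition: str,
    stap_mel: ScoreTable | None = None,
    stap_vir: ScoreTable | None = None,
) -> DeltaFeatures:
    """Assemble the feature matrix for one condition under one variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    ids = cohort.ids
    if variant == "acc_matched":
        tp = condition_tp(condition)
        if tp not in ACC_TIME_POINTS:
            raise ValueError(
                f"no accessibility assay at TP{tp}; "
                f"acc_matched applies only to TPs {ACC_TIME_POINTS}"
            )
        names, mat = _acc_features(cohort, [tp])
    elif variant == "acc_all_tp":
        names, mat = _acc_features(cohort, ACC_TIME_POINTS)
    else:
        if stap_mel is None or stap_vir is None:
            raise ValueError(f"variant {variant!r} needs STAP score tables")
        dstap = delta_table(stap_mel, stap_vir)
        names = [f"StapMel:{condition}", f"dSTAP:{condition}"]
        mat = np.column_stack(
            [stap_mel.column(condition), dstap.column(condition)]
        )
        if variant == "combined":
            acc_names, acc_mat = _acc_features(cohort, ACC_TIME_POINTS)
            names += acc_names
            mat = np.hstack([mat, acc_mat])
    return DeltaFeatures(
        variant=variant, condition=condition, ids=ids, names=names, matrix=mat
    )


def fit_predict_cv(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold SVR predictions; fold shuffling is the only randomness.

    Returns (predictions, fold assignment), each aligned to the input rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} samples, got {n}")
    if np.unique(y).size < 2:
        raise ValueError("degenerate target: constant dChIP")
    pred = np.empty(n)
    fold = np.empty(n, dtype=int)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for f, (tr, te) in enumerate(splitter.split(X)):
        scaler = StandardScaler().fit(X[tr])
        model = SVR(kernel="rbf", C=1.0, epsilon=0.1, gamma=1.0 / p)
        model.fit(scaler.transform(X[tr]), y[tr])
        pred[te] = model.predict(scaler.transform(X[te]))
        fold[te] = f
    return pred, fold


def evaluate_pcc(pred, target) -> CorrelationResult:
    """Pearson correlation (with t-based p) of predictions vs measurements."""
    return pearson_with_pvalue(pred, target)


def extreme_split(target, pct: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the top and bottom floor(n*pct/100) measured values.

    Ties break by stable input order.
    """
    if not (0.0 < pct < 50.0):
        raise ValueError("pct must lie in (0, 50)")
    target = np.asarray(target, dtype=float)
    m = int(np.floor(target.size * pct / 100.0))
    order = np.argsort(target, kind="stable")
    return order[-m:], order[:m]


def evaluate_decile_auroc(
    pred, target, pct: float = 10.0, min_per_class: int = 10
) -> float:
    """AUROC of predictions separating extreme measured changes.

    The top floor(n*pct/100) measured values are positives, the bottom the
    negatives, the middle is discarded.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    pos, neg = extreme_split(target, pct)
    m = pos.size
    if m < min_per_class:
        raise ValueError(
            f"only {m} samples per class at pct={pct}; need {min_per_class}"
        )
    scores = np.concatenate([pred[pos], pred[neg]])
    labels = np.concatenate([np.ones(m, bool), np.zeros(m, bool)])
    return auroc(scores, labels)


def train_stap_models(
    cohort: SyntheticCohort,
    conditions: list[str] | None = None,
    species: str = "mel",
    n_pos: int = 1000,
    n_neg: int = 1000,
    seed: int = 0,
) -> dict[str, StapModel]:
    """Fit a concentration per condition from the cohort's own ChIP scores.

    Positives are the enhancers with the highest normalized ChIP score for
    the condition (with their scores as targets); negatives are random
    background windows, length-matched and assigned target 0 — they carry
    no measured signal and anchor the bottom of the scale.
    """
    conditions = list(conditions or cohort.chip_mel.columns)
    chip = cohort.chip_mel if species == "mel" else cohort.chip_vir
    seqs = cohort.sequences(species)
    ids = np.array(chip.ids)
    seq_length = len(next(iter(seqs.values()))) if seqs else 0
    rng = np.random.default_rng(seed)
    models: dict[str, StapModel] = {}
    for cond in conditions:
        scores = chip.column(cond)
        take = min(n_pos, ids.size)
        top = np.argsort(scores, kind="stable")[::-1][:take]
        pos_seqs = [seqs[i] for i in ids[top]]
        neg = [
            "".join("ACGT"[b] for b in rng.integers(0, 4, size=seq_length))
            for _ in range(min(n_neg, take))
        ]
        train = StapTrainingSet(
            sequences=pos_seqs + neg,
            targets=np.concatenate([scores[top], np.zeros(len(neg))]),
            positive=np.concatenate(
                [np.ones(take, bool), np.zeros(len(neg), bool)]
            ),
        )
        pwm = cohort.config.per_tf_pwm[condition_tf(cond)]
        models[cond] = fit_gamma(train, pwm)
    return models


def compute_stap_tables(
    cohort: SyntheticCohort,
    models_mel: dict[str, StapModel],
    models_vir: dict[str, StapModel] | None = None,
) -> tuple[ScoreTable, ScoreTable]:
    """Normalized STAP score tables for both species."""
    ids = cohort.ids
    stap_mel = stap_score_table(models_mel, cohort.sequences("mel"), ids, "mel")
    stap_vir = stap_score_table(
        models_vir or models_mel, cohort.sequences("vir"), ids, "vir"
    )
    return stap_mel, stap_vir


def run_condition_matrix(
    cohort: SyntheticCohort,
    variants=VARIANTS,
    conditions: list[str] | None = None,
    stap_mel: ScoreTable | None = None,
    stap_vir: ScoreTable | None = None,
    k: int = 5,
    seed: int = 0,
    decile_pct: float = 10.0,
) -> list[DeltaPrediction]:
    """One out-of-fold prediction per (condition, variant).

    ``acc_matched`` is run only for conditions whose time point has an
    accessibility assay; the other variants run for every condition.
    """
    conditions = list(conditions or cohort.chip_mel.columns)
    needs_stap = any(v in ("motif", "combined") for v in variants)
    if needs_stap and (stap_mel is None or stap_vir is None):
        raise ValueError("motif/combined variants need STAP tables")
    dchip = delta_table(cohort.chip_mel, cohort.chip_vir)
    out: list[DeltaPrediction] = []
    for cond in conditions:
        y = dchip.column(cond)
        for variant in variants:
            if variant == "acc_matched" and condition_tp(cond) not in ACC_TIME_POINTS:
                continue
            feats = build_features(cohort, variant, cond, stap_mel, stap_vir)
            pred, fold = fit_predict_cv(feats.matrix, y, k=k, seed=seed)
            pooled = evaluate_pcc(pred, y)
            per_fold = [
                pearson_with_pvalue(pred[fold == f], y[fold == f]).r
                for f in range(k)
            ]
            try:
                dec = evaluate_decile_auroc(pred, y, pct=decile_pct)
            except ValueError:
                dec = float("nan")
            out.append(
                DeltaPrediction(
                    condition=cond,
                    variant=variant,
                    ids=list(feats.ids),
                    predicted=pred,
                    measured=y,
                    fold=fold,
                    pcc=pooled,
                    pcc_fold_mean=float(np.mean(per_fold)),
                    auroc_decile=dec,
                )
            )
    return out
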