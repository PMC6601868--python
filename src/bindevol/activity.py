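"""Enhancer-activity classifiers from 14-condition ChIP profiles.

One gradient-boosted one-vs-rest classifier per activity class (Meso, VM,
SM), trained on the 14-dimensional vector of normalized ChIP scores with
the minority class oversampled to parity by synthetic interpolation
(SMOTE-style), and evaluated by leave-one-out cross-validation with
balanced accuracy. Oversampling happens inside each training split so the
held-out enhancer never leaks into the synthetic points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors
from xgboost import XGBClassifier

from .metrics import ConfusionSummary

__all__ = [
    "ACTIVITY_HYPERPARAMS",
    "ActivityModel",
    "oversample_minority",
    "train_activity_classifier",
    "loocv_confusion",
    "predict_activity",
]

# fixed boosted-tree hyperparameters (logistic objective)
ACTIVITY_HYPERPARAMS = dict(
    learning_rate=0.2,
    n_estimators=50,
    max_depth=4,
    subsample=0.9,
    colsample_bytree=0.8,
)


@dataclass
class ActivityModel:
    """A one-vs-rest boosted-tree classifier for one activity class."""

    cls: str
    booster: XGBClassifier
    seed: int

    def predict_confidence(self, profiles: np.ndarray) -> np.ndarray:
        profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
        if profiles.shape[1] != self.booster.n_features_in_:
            raise ValueError(
                f"profile dimension {profiles.shape[1]} != "
                f"{self.booster.n_features_in_} expected by model"
            )
        return self.booster.predict_proba(profiles)[:, 1]


def oversample_minority(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Bring a binary training set to ~1:1 by synthetic minority points.

    Each synthetic sample lies on the segment between a minority point and
    one of its k minority-class nearest neighbours (uniform interpolation).
    An already balanced input is returned unchanged. Deterministic in seed.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == n_neg:
        return features, labels
    minority_label = n_pos < n_neg
    minority = features[labels == minority_label]
    n_min, n_maj = min(n_pos, n_neg), max(n_pos, n_neg)
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples to oversample")
    rng = np.random.default_rng(seed)
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    _, idx = nn.kneighbors(minority)  # column 0 is the point itself
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    u = rng.random(size=(n_new, 1))
    anchors = minority[base]
    partners = minority[idx[base, pick]]
    synthetic = anchors + u * (partners - anchors)
    aug_x = np.vstack([features, synthetic])
    aug_y = np.concatenate([labels, np.full(n_new, minority_label)])
    return aug_x, aug_y


def train_activity_classifier(
    profiles: np.ndarray,
    labels: np.ndarray,
    cls: str,
    seed: int = 0,
) -> ActivityModel:
    """Train the one-vs-rest classifier for one class on oversampled data.

    ``labels`` is boolean membership of ``cls``. Raises on single-class
    input.
    """
    profiles = np.asarray(profiles, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("single-class input: cannot train a discriminator")
    x, y = oversample_minority(profiles, labels, seed=seed)
    booster = XGBClassifier(
        objective="binary:logistic",
        random_state=seed,
        tree_method="hist",
        n_jobs=1,
        verbosity=0,
        **ACTIVITY_HYPERPARAMS,
    )
    booster.fit(x, y.astype(int))
    return ActivityModel(cls=cls, booster=booster, seed=seed)


def loocv_confusion(
    profiles: np.ndarray,
    labels: np.ndarray,
    cls: str | None = None,
    threshold: float = 0.5,
    seed: int = 0,
) -> tuple[ConfusionSummary, np.ndarray]:
    """Leave-one-out confusion summary at a confidence threshold.

    Each enhancer is scored by a model trained on all the others (with
    oversampling done inside every training split). Returns the confusion
    counts and the vector of held-out confidences.
    """
    profiles = np.asarray(profiles, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n = labels.size
    if n < 3:
        raise ValueError("need at least 3 samples for leave-one-out")
    conf = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = train_activity_classifier(
            profiles[keep], labels[keep], cls or "class", seed=seed
        )
        conf[i] = model.predict_confidence(profiles[i : i + 1])[0]
    calls = conf >= threshold
    return (
        ConfusionSummary(
            tn=int(np.sum(~calls & ~labels)),
            fn=int(np.sum(~calls & labels)),
            tp=int(np.sum(calls & labels)),
            fp=int(np.sum(calls & ~labels)),
        ),
        conf,
    )


def predict_activity(
    models: dict[str, ActivityModel], profiles: np.ndarray
) -> dict[str, np.ndarray]:
    """Confidence A_C per class per enhancer (classes scored independently)."""
    return {cls: m.predict_confidence(profiles) for cls, m in models.items()}
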