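"""Within-subject linear SVM decoders of affect and ensemble prediction.

Normative Likert scores are binarized at the scale midpoint (5 on 1-9) to
classes {+1, -1}; a soft-margin linear SVM (C = 1, tol = 1e-3) is fit per
subject and affect dimension.  Validation is leave-one-out with repeated
class-balanced subsampling of the training folds so the null classification
rate stays at 50%.  Predictions on new brain states are signed hyperplane
distances; out-of-sample ensembles average the distances over the models of
all training subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from ._seeds import rng_for
from .types import LinearDecoder

__all__ = [
    "AffectClassLabels",
    "CVResult",
    "binarize_scores",
    "fit_classifier",
    "hyperplane_distance",
    "loocv_balanced_accuracy",
    "ensemble_decode",
]

LIKERT_MIDPOINT = 5.0


@dataclass
class AffectClassLabels:
    labels: np.ndarray  # {+1, -1} per trial
    source_scores: np.ndarray
    dimension: str  # "valence" | "arousal"

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.source_scores = np.asarray(self.source_scores, dtype=float)
        if self.labels.shape != self.source_scores.shape:
            raise ValueError("labels and source scores must align")
        if not np.isin(self.labels, (-1, 1)).all():
            raise ValueError("labels must be +1/-1")


@dataclass
class CVResult:
    accuracy: float
    fold_predictions: np.ndarray  # (folds, resamples) predicted labels
    n_resamples: int
    null_rate: float = 0.5
    meta: dict = field(default_factory=dict)


def binarize_scores(
    scores, dimension: str = "valence", midpoint: float = LIKERT_MIDPOINT
) -> AffectClassLabels:
    """Scores strictly above the Likert midpoint map to +1, else -1."""
    scores = np.asarray(scores, dtype=float)
    if ((scores < 1.0) | (scores > 9.0)).any():
        raise ValueError("scores must lie in [1, 9]")
    labels = np.where(scores > midpoint, 1, -1)
    return AffectClassLabels(labels, scores, dimension)


def fit_classifier(
    features: np.ndarray,
    labels: AffectClassLabels,
    penalty: float = 1.0,
    tolerance: float = 1e-3,
    target: tuple[str, int] | None = None,
    training_meta: dict | None = None,
) -> LinearDecoder:
    """Soft-margin linear SVM; returns primal weights and offset."""
    features = np.asarray(features, dtype=float)
    y = labels.labels
    if features.shape[0] != y.shape[0]:
        raise ValueError("feature rows must match label count")
    if features.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit a classifier")
    svc = SVC(kernel="linear", C=penalty, tol=tolerance)
    svc.fit(features, y)
    # sklearn orders classes [-1, +1]: decision_function > 0 predicts +1
    return LinearDecoder(
        weights=svc.coef_[0],
        offset=float(svc.intercept_[0]),
        target=target or (labels.dimension, 0),
        model_form="classifier",
        training_meta=dict(training_meta or {}, n_samples=int(y.size)),
    )


def hyperplane_distance(model: LinearDecoder, brain_state: np.ndarray) -> float:
    """Signed geometric distance (w.x + b)/||w||; positive predicts +1."""
    if model.model_form != "classifier":
        raise ValueError("hyperplane distance is defined for classifiers")
    brain_state = np.asarray(brain_state, dtype=float)
    if brain_state.shape[-1] != model.weights.shape[0]:
        raise ValueError("brain state dimension does not match model")
    return float(model.predict(brain_state)) if brain_state.ndim == 1 else model.predict(brain_state)


def _balanced_subsample(
    y: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a class-balanced subsample (majority downsampled)."""
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == -1)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("balanced subsample impossible: a class is empty")
    k = min(pos.size, neg.size)
    keep_pos = rng.choice(pos, size=k, replace=False)
    keep_neg = rng.choice(neg, size=k, replace=False)
    return np.sort(np.concatenate([keep_pos, keep_neg]))


def loocv_balanced_accuracy(
    features: np.ndarray,
    labels: AffectClassLabels,
    n_resamples: int = 30,
    seed: int = 0,
    penalty: float = 1.0,
    tolerance: float = 1e-3,
) -> CVResult:
    """Leave-one-out CV with class-balanced resampling of each training fold.

    For each held-out sample the remaining pairs are subsampled
    ``n_resamples`` times to equal class counts before fitting, so chance
    performance is exactly 50% regardless of class imbalance.  Accuracy is
    the mean over all (fold x resample) predictions.
    """
    features = np.asarray(features, dtype=float)
    y = labels.labels
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("need >= 2 samples per class for balanced LOOCV")
    n = y.size
    preds = np.zeros((n, n_resamples), dtype=int)
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        rng = rng_for(seed, "loocv", i)
        for r in range(n_resamples):
            keep = rest[_balanced_subsample(y[rest], rng)]
            model = fit_classifier(
                features[keep],
                AffectClassLabels(y[keep], labels.source_scores[keep], labels.dimension),
                penalty=penalty,
                tolerance=tolerance,
            )
            preds[i, r] = 1 if model.predict(features[i]) > 0 else -1
    accuracy = float((preds == y[:, None]).mean())
    return CVResult(
        accuracy=accuracy,
        fold_predictions=preds,
        n_resamples=n_resamples,
        meta={"dimension": labels.dimension, "n_folds": n},
    )


def ensemble_decode(
    models: list[LinearDecoder], brain_state: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Ensemble-average prediction over models, with a t-based 95% CI.

    All models must share a target.  For classifiers the averaged quantity
    is the signed hyperplane distance; for regressors the linear prediction.
    """
    if len(models) < 2:
        raise ValueError("need >= 2 models for an ensemble CI")
    targets = {m.target for m in models}
    if len(targets) > 1:
        raise ValueError(f"mixed ensemble targets: {sorted(targets)}")
    preds = np.array([float(m.predict(np.asarray(brain_state))) for m in models])
    mean = float(preds.mean())
    sem = preds.std(ddof=1) / np.sqrt(preds.size)
    if sem == 0.0:
        return mean, (mean, mean)
    tcrit = stats.t.ppf(0.975, preds.size - 1)
    return mean, (mean - tcrit * sem, mean + tcrit * sem)


def ensemble_decode_matrix(
    models: list[LinearDecoder], brain_states: np.ndarray
) -> np.ndarray:
    """Vectorized ensemble means for many brain states (rows)."""
    if len(models) < 1:
        raise ValueError("need at least one model")
    targets = {m.target for m in models}
    if len(targets) > 1:
        raise ValueError(f"mixed ensemble targets: {sorted(targets)}")
    preds = np.column_stack([m.predict(np.asarray(brain_states)) for m in models])
    return preds.mean(axis=1)
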