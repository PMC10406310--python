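"""Temporal derivatives of decoded affect and their neural decoders.

First and second derivatives are taken by center divided differences in
volume units (no TR rescaling):

    dx/dt[t]     = (x[t+1] - x[t-1]) / 2
    d2x/dt2[t]   = (dx/dt[t+1] - dx/dt[t-1]) / 2

NaNs propagate through the stencil and endpoints are NaN, so the second
derivative effectively uses a 5-point stencil of x.  Linear support-vector
regression models are then fit per subject, mapping per-volume brain states
(the across-iteration mean self-task betas) directly onto the derivative
series; together with the state decoders these form the neurally
constrained ODE of resting affect processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .decoders import ensemble_decode_matrix
from .types import LinearDecoder

__all__ = [
    "DerivativeSeries",
    "central_first_derivative",
    "central_second_derivative",
    "derivative_series",
    "fit_derivative_decoder",
    "fit_subject_derivative_decoders",
    "loso_derivative_predictions",
    "crossvalidate_derivative_decoders",
]


@dataclass
class DerivativeSeries:
    """First/second derivative of one decoded affect dimension (per volume)."""

    d1: np.ndarray  # units per volume
    d2: np.ndarray  # units per volume^2
    dimension: str


def _central_difference(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for a central difference")
    out = np.full(x.shape, np.nan)
    out[1:-1] = (x[2:] - x[:-2]) / 2.0
    return out


def central_first_derivative(x: np.ndarray) -> np.ndarray:
    """(x[t+1] - x[t-1]) / 2; NaN at endpoints and around NaN inputs."""
    return _central_difference(x)


def central_second_derivative(d1: np.ndarray) -> np.ndarray:
    """Central difference of the first-derivative series."""
    return _central_difference(d1)


def derivative_series(value: np.ndarray, dimension: str = "") -> DerivativeSeries:
    d1 = central_first_derivative(value)
    d2 = central_second_derivative(d1)
    return DerivativeSeries(d1=d1, d2=d2, dimension=dimension)


def fit_derivative_decoder(
    brain_states: np.ndarray,
    targets: np.ndarray,
    target: tuple[str, int],
    penalty: float = 1.0,
    epsilon: float | None = None,
    tolerance: float = 1e-3,
    training_meta: dict | None = None,
) -> LinearDecoder:
    """Linear epsilon-SVR of a derivative series on brain states.

    Rows where either the target or any feature is NaN are dropped; by
    default epsilon is one tenth of the target standard deviation.
    """
    X = np.asarray(brain_states, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("feature rows must match target length")
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    if ok.sum() < 10:
        raise ValueError(f"need >= 10 finite (state, target) pairs, got {ok.sum()}")
    X, y = X[ok], y[ok]
    if epsilon is None:
        sd = float(y.std())
        epsilon = 0.1 * sd if sd > 0 else 0.0
    svr = SVR(kernel="linear", C=penalty, epsilon=epsilon, tol=tolerance)
    svr.fit(X, y)
    return LinearDecoder(
        weights=svr.coef_[0],
        offset=float(svr.intercept_[0]),
        target=target,
        model_form="regressor",
        training_meta=dict(training_meta or {}, n_samples=int(ok.sum())),
    )


def _subject_targets(decode) -> dict[tuple[str, int], np.ndarray]:
    """Numerical derivative targets of one subject's decoded series."""
    out = {}
    for dim, ser in decode.series.items():
        deriv = derivative_series(ser.value, dim)
        out[(dim, 1)] = deriv.d1
        out[(dim, 2)] = deriv.d2
    return out


def fit_subject_derivative_decoders(
    decode, subject_id: str
) -> dict[tuple[str, int], LinearDecoder]:
    """Fit all four derivative decoders (2 dims x 2 orders) for one subject."""
    models = {}
    for tgt, y in _subject_targets(decode).items():
        models[tgt] = fit_derivative_decoder(
            decode.features, y, target=tgt, training_meta={"subject_id": subject_id}
        )
    return models


def loso_derivative_predictions(
    subject_decodes: dict[str, "RestingDecode"],
) -> pd.DataFrame:
    """Leave-one-subject-out decoded derivatives for every usable volume.

    Each hold-out subject's per-volume brain states are decoded by the
    ensemble mean of the other subjects' derivative models.  Rows cover all
    volumes with finite features; the ``true`` numerical derivative may be
    NaN there (e.g. next to trimmed or outlier volumes) — consumers that
    need paired data filter on it.
    """
    sids = sorted(subject_decodes)
    if len(sids) < 2:
        raise ValueError("need >= 2 subjects")
    fitted = {
        sid: fit_subject_derivative_decoders(subject_decodes[sid], sid)
        for sid in sids
    }
    rows = []
    for sid in sids:
        decode = subject_decodes[sid]
        targets = _subject_targets(decode)
        feat_ok = np.isfinite(decode.features).all(axis=1)
        X = np.where(np.isfinite(decode.features), decode.features, 0.0)
        for tgt, y in targets.items():
            models = [fitted[o][tgt] for o in sids if o != sid]
            pred = ensemble_decode_matrix(models, X)
            for v in np.flatnonzero(feat_ok):
                rows.append((sid, tgt[0], tgt[1], int(v), float(y[v]), float(pred[v])))
    return pd.DataFrame(
        rows, columns=["subject", "dimension", "order", "volume", "true", "decoded"]
    )


def crossvalidate_derivative_decoders(
    subject_decodes: dict[str, "RestingDecode"],
    scheme: str = "leave-one-subject-out",
) -> pd.DataFrame:
    """Out-of-sample validation of derivative decoders across a cohort.

    ``leave-one-subject-out``: each hold-out subject's derivatives are
    decoded by the ensemble mean of the other subjects' models applied to
    the hold-out brain states.  ``within-subject``: leave-one-volume-out
    within each subject.  Returns a long table (subject, dimension, order,
    volume, true, decoded) restricted to volumes where the numerical
    derivative is finite and a prediction exists.
    """
    sids = sorted(subject_decodes)
    if len(sids) < 2:
        raise ValueError("need >= 2 subjects")
    rows = []
    if scheme in ("leave-one-subject-out", "loso"):
        table = loso_derivative_predictions(subject_decodes)
        return table[np.isfinite(table["true"])].reset_index(drop=True)
    elif scheme in ("within-subject", "loocv"):
        for sid in sids:
            decode = subject_decodes[sid]
            feat_ok = np.isfinite(decode.features).all(axis=1)
            for tgt, y in _subject_targets(decode).items():
                ok = np.flatnonzero(np.isfinite(y) & feat_ok)
                for v in ok:
                    train = ok[ok != v]
                    model = fit_derivative_decoder(
                        decode.features[train], y[train], target=tgt,
                        training_meta={"subject_id": sid},
                    )
                    pred = float(model.predict(decode.features[v]))
                    rows.append((sid, tgt[0], tgt[1], int(v), float(y[v]), pred))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return pd.DataFrame(
        rows, columns=["subject", "dimension", "order", "volume", "true", "decoded"]
    )
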