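"""Single-trial brain-state estimation via beta-series LSS regression.

The beta-series method fits one activation estimate per trial so that
trial-level variance survives into the decoding features.  We use the
classic least-squares-separate (LSS) variant: for each trial a GLM is
solved with (a) the regressor of that trial, (b) a single regressor summing
all other trials, (c) Legendre drift polynomials, (d) optional confounds.
The per-trial coefficient from model (a) is that trial's beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial import legendre

from .hrf import boxcar, double_gamma_hrf
from .types import BoldRun, MaskGeometry, TrialEvent

__all__ = [
    "BetaSeries",
    "hrf_regressor",
    "drift_basis",
    "lss_solve",
    "nuisance_regress",
    "group_gm_mask",
]


@dataclass
class BetaSeries:
    """Trial x voxel activation estimates plus the trial ordering."""

    betas: np.ndarray  # (trials, voxels)
    trial_index: list[str]

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape[0] != len(self.trial_index):
            raise ValueError("row count must equal number of modeled events")
        if not np.isfinite(self.betas).all():
            raise ValueError("beta estimates contain non-finite values")


def hrf_regressor(
    events: Sequence[TrialEvent], n_volumes: int, tr: float
) -> np.ndarray:
    """HRF-convolved boxcar regressor for a set of events, sampled at TR.

    Peak-normalized to 1 (so betas are in percent-signal-change units at the
    response peak).  An event extending past the run end is truncated with a
    warning; an empty event list yields a zero column.
    """
    col = np.zeros(n_volumes)
    if not events:
        return col
    run_end = n_volumes * tr
    stim = np.zeros(n_volumes)
    for e in events:
        if e.onset >= run_end:
            warnings.warn(
                f"event at {e.onset:.1f}s starts after run end; dropped",
                stacklevel=2,
            )
            continue
        if e.onset + e.duration > run_end:
            warnings.warn(
                f"event at {e.onset:.1f}s extends beyond run end; truncated",
                stacklevel=2,
            )
        stim += boxcar(e.onset, e.duration, n_volumes, tr)
    h = double_gamma_hrf(tr)
    col = np.convolve(stim, h)[:n_volumes]
    peak = np.abs(col).max()
    return col / peak if peak > 0 else col


def drift_basis(n_volumes: int, order: int) -> np.ndarray:
    """Legendre polynomial drift columns, orders 0..order, on [-1, 1]."""
    t = np.linspace(-1.0, 1.0, n_volumes)
    return np.column_stack(
        [legendre.legval(t, np.eye(order + 1)[k]) for k in range(order + 1)]
    )


def _check_rank(design: np.ndarray, roles: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient design matrix "
            f"(rank {rank} < {design.shape[1]} columns; roles: {roles})"
        )


def lss_solve(
    run: BoldRun,
    events: Sequence[TrialEvent],
    confounds: np.ndarray | None = None,
    drift_order: int = 2,
) -> BetaSeries:
    """Estimate one beta per event per voxel via least-squares-separate.

    For event i the design holds [regressor_i, sum of all other event
    regressors, drift polynomials, confounds]; the returned beta is the
    coefficient of regressor_i.  With a single event this degenerates to an
    ordinary two-part GLM (trial + baseline).
    """
    n_vol = run.n_volumes
    events = list(events)
    if not events:
        raise ValueError("no events to model")
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n_vol:
            raise ValueError("confound rows must match run volumes")

    single = np.column_stack(
        [hrf_regressor([e], n_vol, run.tr) for e in events]
    )  # (volumes, trials)
    if (np.abs(single).max(axis=0) == 0).any():
        bad = [e.stimulus_id for e, z in zip(events, np.abs(single).max(axis=0) == 0) if z]
        raise ValueError(f"all-zero trial regressor(s) for events {bad}")
    total = single.sum(axis=1)
    baseline_cols = [drift_basis(n_vol, drift_order)]
    baseline_roles = ["drift"] * (drift_order + 1)
    if confounds is not None and confounds.shape[1] > 0:
        baseline_cols.append(confounds)
        baseline_roles += ["confound"] * confounds.shape[1]
    baseline = np.column_stack(baseline_cols)

    Y = run.data.T  # (volumes, voxels)
    betas = np.empty((len(events), run.data.shape[0]))
    for i in range(len(events)):
        cols = [single[:, i]]
        roles = ["trial-of-interest"]
        if len(events) > 1:
            cols.append(total - single[:, i])
            roles.append("other-trials")
        design = np.column_stack(cols + [baseline])
        _check_rank(design, roles + baseline_roles)
        coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
        betas[i] = coef[0]
    return BetaSeries(betas, [e.stimulus_id for e in events])


def nuisance_regress(run: BoldRun, confounds: np.ndarray | None) -> BoldRun:
    """Residualize each voxel against confound columns plus an intercept."""
    n_vol = run.n_volumes
    if confounds is None or np.size(confounds) == 0:
        resid = run.data - run.data.mean(axis=1, keepdims=True)
        return BoldRun(resid, run.tr, run.geometry)
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[0] != n_vol:
        raise ValueError("confound rows must match run volumes")
    X = np.column_stack([np.ones(n_vol), confounds])
    Y = run.data.T
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return BoldRun((Y - X @ coef).T, run.tr, run.geometry)


def group_gm_mask(
    subject_masks: Sequence[np.ndarray], threshold: float = 0.5
) -> tuple[MaskGeometry, np.ndarray]:
    """Group gray-matter mask: include voxels GM in >= threshold of subjects.

    Returns the group geometry plus the per-voxel inclusion fraction grid.
    """
    if not len(subject_masks):
        raise ValueError("no subject masks provided")
    masks = [np.asarray(m).astype(bool) for m in subject_masks]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("subject masks must share a grid shape")
    fraction = np.mean(masks, axis=0)
    return MaskGeometry.from_mask(fraction >= threshold), fraction
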