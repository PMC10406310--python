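"""Moment-to-moment affect decoding of resting-state runs.

A task-free run has no events, so "self-task" stimuli — fictitious onsets
placed at randomly sampled volume acquisition times — let the beta-series
machinery produce per-volume brain states.  Each iteration samples
``n_stimuli`` volume times without replacement from the decodable window
(the first 5 and final 10 volumes are discarded), extracts LSS betas, and
decodes each beta with the ensemble-average hyperplane distance over the
training subjects' classifiers.  Grouping decodings by volume across
iterations yields a per-volume estimate with a t-based 95% CI; gross
outliers are screened by a Bonferroni-corrected median/MAD rule and
replaced with NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._seeds import rng_for
from .betaseries import lss_solve
from .decoders import ensemble_decode_matrix
from .types import BoldRun, LinearDecoder, TrialEvent

__all__ = [
    "TRIM_START",
    "TRIM_END",
    "SelfTaskPlan",
    "DecodedAffectSeries",
    "RestingDecode",
    "plan_self_task",
    "decode_resting_run",
    "mad_outlier_mask",
]

#: volumes discarded at the start / end of every resting acquisition
TRIM_START = 5
TRIM_END = 10

#: consistency of the MAD with the Gaussian standard deviation
MAD_TO_SD = 1.4826


@dataclass(frozen=True)
class SelfTaskPlan:
    """Self-task onset times (seconds) for each decoding iteration."""

    iterations: tuple[tuple[float, ...], ...]
    n_stimuli_per_iter: int
    seed: int

    def __post_init__(self):
        for onsets in self.iterations:
            if len(onsets) != self.n_stimuli_per_iter:
                raise ValueError("every iteration must hold n_stimuli_per_iter onsets")
            if len(set(onsets)) != len(onsets):
                raise ValueError("onsets within an iteration must be distinct")


@dataclass
class DecodedAffectSeries:
    """Per-volume decoded affect for one dimension, with CIs and NaN mask."""

    value: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_samples: np.ndarray
    tr: float
    dimension: str
    outlier: np.ndarray | None = None  # True where the MAD rule fired


@dataclass
class RestingDecode:
    """Full decoding of one resting run: both dimensions plus features.

    ``features`` holds the across-iteration mean self-task beta per volume
    (NaN rows where a volume was trimmed or never sampled); these are the
    brain states later used to fit derivative decoders.
    """

    series: dict[str, DecodedAffectSeries]
    features: np.ndarray  # (volumes, voxels)
    plan: SelfTaskPlan
    meta: dict = field(default_factory=dict)


def decodable_volumes(n_volumes: int) -> np.ndarray:
    """Volume indices surviving the (first 5, final 10) trim."""
    if n_volumes <= TRIM_START + TRIM_END:
        raise ValueError("run too short for the trim window")
    return np.arange(TRIM_START, n_volumes - TRIM_END)


def plan_self_task(
    n_volumes: int,
    tr: float = 2.0,
    n_stimuli: int = 100,
    n_iterations: int = 30,
    seed: int = 0,
) -> SelfTaskPlan:
    """Sample self-task onsets: n_stimuli distinct volume times per iteration.

    Onsets snap to volume acquisition times (multiples of TR) inside the
    decodable window; sampling is without replacement within an iteration
    and independent across iterations.
    """
    window = decodable_volumes(n_volumes)
    if n_stimuli > window.size:
        raise ValueError(
            f"decodable window holds {window.size} volumes < n_stimuli={n_stimuli}"
        )
    rng = rng_for(seed, "self-task-plan")
    iters = []
    for _ in range(n_iterations):
        vols = np.sort(rng.choice(window, size=n_stimuli, replace=False))
        iters.append(tuple(float(v * tr) for v in vols))
    return SelfTaskPlan(tuple(iters), n_stimuli, seed)


def mad_outlier_mask(series: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Median/MAD outlier screen at a Bonferroni-corrected Gaussian threshold.

    x is flagged iff |x - median| / (1.4826 * MAD) exceeds the two-sided
    normal quantile at alpha / n_finite.  NaNs are ignored and never
    flagged.  A zero MAD with non-constant data disables the screen with a
    warning (the rule would flag every off-median value).
    """
    series = np.asarray(series, dtype=float)
    mask = np.zeros(series.shape, dtype=bool)
    finite = np.isfinite(series)
    n = int(finite.sum())
    if n < 5:
        raise ValueError("need >= 5 finite values for outlier screening")
    vals = series[finite]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    if mad == 0.0:
        if np.ptp(vals) > 0:
            warnings.warn("MAD is zero with non-constant data; no outliers flagged")
        return mask
    zcrit = stats.norm.ppf(1.0 - alpha / (2.0 * n))
    z = np.abs(series - med) / (MAD_TO_SD * mad)
    mask[finite] = z[finite] > zcrit
    return mask


def decode_resting_run(
    run: BoldRun,
    plan: SelfTaskPlan,
    training_models: dict[str, list[LinearDecoder]],
    hold_out_subject: str | None = None,
    confounds: np.ndarray | None = None,
    drift_order: int = 2,
    stim_duration: float = 2.0,
    outlier_alpha: float = 0.05,
) -> RestingDecode:
    """Decode a hold-out resting run with out-of-sample ensemble models.

    ``training_models`` maps each affect dimension to the list of state
    classifiers of the *training* subjects; a model carrying the hold-out
    subject's id is rejected (out-of-sample purity).
    """
    for dim, models in training_models.items():
        if len(models) < 2:
            raise ValueError(f"need >= 2 training models for dimension {dim!r}")
        if hold_out_subject is not None:
            culprits = [m for m in models if m.subject_id == hold_out_subject]
            if culprits:
                raise ValueError(
                    f"hold-out subject {hold_out_subject!r} appears among the "
                    f"training models for {dim!r}"
                )

    n_vol = run.n_volumes
    dims = list(training_models)
    grouped: dict[str, list[list[float]]] = {d: [[] for _ in range(n_vol)] for d in dims}
    feat_sum = np.zeros((n_vol, run.data.shape[0]))
    feat_count = np.zeros(n_vol)

    for onsets in plan.iterations:
        events = [
            TrialEvent(
                onset=o,
                duration=stim_duration,
                stimulus_id=f"self{int(round(o / run.tr)):04d}",
                valence=5.0,
                arousal=5.0,
            )
            for o in onsets
        ]
        betas = lss_solve(run, events, confounds=confounds, drift_order=drift_order)
        vols = [int(round(o / run.tr)) for o in onsets]
        decoded = {d: ensemble_decode_matrix(training_models[d], betas.betas) for d in dims}
        for j, v in enumerate(vols):
            feat_sum[v] += betas.betas[j]
            feat_count[v] += 1
            for d in dims:
                grouped[d][v].append(float(decoded[d][j]))

    window = decodable_volumes(n_vol)
    in_window = np.zeros(n_vol, dtype=bool)
    in_window[window] = True

    features = np.full((n_vol, run.data.shape[0]), np.nan)
    sampled = (feat_count > 0) & in_window
    features[sampled] = feat_sum[sampled] / feat_count[sampled, None]

    series: dict[str, DecodedAffectSeries] = {}
    for d in dims:
        value = np.full(n_vol, np.nan)
        lo = np.full(n_vol, np.nan)
        hi = np.full(n_vol, np.nan)
        n_samples = np.zeros(n_vol, dtype=int)
        for v in range(n_vol):
            samples = grouped[d][v]
            n_samples[v] = len(samples)
            if not in_window[v] or not samples:
                continue
            arr = np.asarray(samples)
            value[v] = arr.mean()
            if arr.size >= 2:
                sem = arr.std(ddof=1) / np.sqrt(arr.size)
                tcrit = stats.t.ppf(0.975, arr.size - 1)
                lo[v], hi[v] = value[v] - tcrit * sem, value[v] + tcrit * sem
        out_mask = mad_outlier_mask(value, alpha=outlier_alpha)
        value[out_mask] = np.nan
        lo[out_mask] = np.nan
        hi[out_mask] = np.nan
        series[d] = DecodedAffectSeries(
            value=value,
            ci_low=lo,
            ci_high=hi,
            n_samples=n_samples,
            tr=run.tr,
            dimension=d,
            outlier=out_mask,
        )
    return RestingDecode(
        series=series,
        features=features,
        plan=plan,
        meta={"hold_out_subject": hold_out_subject, "n_iterations": len(plan.iterations)},
    )
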