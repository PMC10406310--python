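"""Synthetic multi-subject fMRI cohorts with known affect dynamics.

Every downstream stage of the pipeline — beta-series extraction, affect
classifiers, resting-state ensemble decoding, derivative (ODE) decoders,
closed-loop simulation and encoding maps — is validated against data from
this generator, whose latent state and voxelwise encoding patterns are known
exactly.

The generative model
--------------------
Each affect dimension (valence, arousal) follows an independent damped
stochastic harmonic oscillator

    x'' = -omega^2 x - gamma x' + eps(t),

with ``eps`` piecewise-constant white forcing redrawn once per volume.  This
is the simplest latent process with non-trivial, decodable second-order
structure; it is a test harness, not a claim about the brain.  The system is
integrated exactly (matrix exponential per volume interval), so the recorded
state, velocity and acceleration series are the analytic derivatives of the
simulated path at volume times.

Voxelwise encodings are random unit-norm patterns — one per quantity
(state, first derivative, second derivative, per dimension) — scaled by
per-quantity amplitudes; derivative encodings are distinct patterns and by
default carry larger amplitudes than the state, so the regime in which
higher-order dynamics are more strongly encoded than the state itself is
realizable.  Subject patterns are the group pattern plus a random
perturbation.  The neural amplitude time courses are convolved with the
canonical double-gamma HRF, and Gaussian noise plus Legendre-polynomial
drift are added before per-voxel mean-centering (percent-signal-change
convention).

Task runs present ~2 s image stimuli with 2-6 s uniform inter-trial
intervals; each trial drives the state patterns with amplitude
``(score - 5) / 4`` so the normative valence/arousal scores span both
binary classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm
from numpy.polynomial import legendre

from ._seeds import rng_for
from .hrf import convolve_amplitudes, boxcar
from .io import ensure_dir, save_bold_run, save_mask, write_events
from .types import BoldRun, MaskGeometry, TrialEvent

__all__ = [
    "LatentDynamicsParams",
    "GroundTruth",
    "CohortConfig",
    "QUANTITIES",
    "generate_latent_trajectory",
    "generate_task_events",
    "generate_encoding_patterns",
    "render_bold",
    "generate_cohort",
    "ball_mask",
    "subject_ids",
    "task_run_volumes",
    "trial_amplitude_course",
]

#: decodable quantity keys: state, 1st and 2nd derivative per affect dimension
QUANTITIES = ("v", "a", "dv", "da", "d2v", "d2a")

DIMENSIONS = ("valence", "arousal")

#: quantity key for (dimension, derivative order)
QUANTITY_OF = {
    ("valence", 0): "v",
    ("arousal", 0): "a",
    ("valence", 1): "dv",
    ("arousal", 1): "da",
    ("valence", 2): "d2v",
    ("arousal", 2): "d2a",
}


@dataclass(frozen=True)
class LatentDynamicsParams:
    """Damped stochastic harmonic oscillator parameters (volume time units).

    natural_frequency
        omega, rad/volume.  Default 0.3 rad/volume (period ~21 volumes,
        i.e. ~42 s at TR = 2 s) — slow spontaneous affect fluctuation.
    damping
        gamma, 1/volume.  Light damping (0.05) keeps noise-excited
        oscillation alive over a run.
    process_noise_sd
        Standard deviation of the piecewise-constant random forcing.
    initial_state
        (value, velocity) applied to both affect dimensions.
    """

    natural_frequency: float = 0.3
    damping: float = 0.05
    process_noise_sd: float = 0.1
    initial_state: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.damping < 0:
            raise ValueError("damping must be >= 0")
        if self.process_noise_sd < 0:
            raise ValueError("process_noise_sd must be >= 0")
        if self.damping == 0 and self.process_noise_sd > 0:
            raise ValueError(
                "unstable parameter set: zero damping with nonzero process "
                "noise lets oscillation energy grow without bound"
            )

    def transition_matrix(self, dt: float = 1.0) -> np.ndarray:
        """One-step (dt volumes) state-transition matrix of (x, x')."""
        w, g = self.natural_frequency, self.damping
        A = np.array([[0.0, 1.0], [-w * w, -g]])
        return expm(A * dt)


@dataclass
class GroundTruth:
    """Latent trajectories and voxel encoding patterns of one subject."""

    latent: np.ndarray  # (volumes, 2): state per dimension
    latent_d1: np.ndarray  # analytic dx/dt at volume times
    latent_d2: np.ndarray  # analytic d2x/dt2 at volume times
    encoding_patterns: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self):
        sizes = {v.shape for v in self.encoding_patterns.values()}
        if len(sizes) > 1:
            raise ValueError("encoding patterns have mismatched voxel dimensions")


def generate_latent_trajectory(
    params: LatentDynamicsParams, n_volumes: int, seed: int
) -> GroundTruth:
    """Simulate the latent oscillator, one sample per volume, both dimensions.

    The forcing is held constant within each volume interval and the linear
    system is propagated by its exact matrix exponential, so the returned
    first/second derivative series are the true derivatives of the path at
    volume times (acceleration uses the forcing active on [t, t+1)).
    """
    if n_volumes < 5:
        raise ValueError("n_volumes must be >= 5")
    w, g, sd = params.natural_frequency, params.damping, params.process_noise_sd
    # exact propagator for z = (x, x', u) with constant unit input channel
    M = np.array([[0.0, 1.0, 0.0], [-w * w, -g, 1.0], [0.0, 0.0, 0.0]])
    E = expm(M)
    rng = rng_for(seed, "latent")
    eps = rng.normal(0.0, sd, size=(n_volumes, 2)) if sd > 0 else np.zeros((n_volumes, 2))

    x = np.zeros((n_volumes, 2))
    v = np.zeros((n_volumes, 2))
    a = np.zeros((n_volumes, 2))
    # state columns are the two affect dimensions; rows are (x, x')
    state = np.array([[params.initial_state[0]] * 2, [params.initial_state[1]] * 2])
    for t in range(n_volumes):
        x[t] = state[0]
        v[t] = state[1]
        a[t] = -w * w * state[0] - g * state[1] + eps[t]
        state = E[:2, :2] @ state + np.outer(E[:2, 2], eps[t])
    return GroundTruth(latent=x, latent_d1=v, latent_d2=a)


def _default_score_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform continuous Likert pairs over [1, 9]^2 (normative-score style)."""
    return rng.uniform(1.0, 9.0, size=(n, 2))


def generate_task_events(
    n_trials: int,
    stim_duration: float = 2.0,
    iti_range: tuple[float, float] = (2.0, 6.0),
    score_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
) -> list[TrialEvent]:
    """Tile affect-induction trials: 2 s stimuli, uniform 2-6 s ITIs.

    Scores are drawn from ``score_sampler`` (default: uniform on [1, 9] for
    both dimensions).  If either affect dimension ends up with a single
    binary class (all scores on one side of the Likert midpoint) a warning
    is emitted — downstream classifiers need both classes.
    """
    if iti_range[0] < 0:
        raise ValueError("iti_range minimum must be >= 0")
    if iti_range[1] < iti_range[0]:
        raise ValueError("iti_range must be (low, high) with low <= high")
    rng = rng_for(seed, "task-events")
    sampler = score_sampler or _default_score_sampler
    scores = np.asarray(sampler(rng, n_trials), dtype=float)
    itis = rng.uniform(iti_range[0], iti_range[1], size=n_trials)
    events = []
    onset = 0.0
    for i in range(n_trials):
        events.append(
            TrialEvent(
                onset=onset,
                duration=stim_duration,
                stimulus_id=f"stim{i:03d}",
                valence=float(scores[i, 0]),
                arousal=float(scores[i, 1]),
            )
        )
        onset += stim_duration + float(itis[i])
    for d, name in enumerate(("valence", "arousal")):
        sides = scores[:, d] > 5.0
        if sides.all() or not sides.any():
            warnings.warn(
                f"all {name} scores fall in a single binary class",
                stacklevel=2,
            )
    return events


def ball_mask(grid_shape: tuple[int, int, int], radius: float | None = None) -> MaskGeometry:
    """Centered ball mask on a small 3-D grid (real geometry for clustering)."""
    shape = tuple(grid_shape)
    if radius is None:
        radius = min(shape) / 2.0 + 0.1
    center = (np.array(shape) - 1) / 2.0
    grids = np.indices(shape)
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return MaskGeometry.from_mask(dist2 <= radius**2)


def generate_encoding_patterns(
    n_voxels: int,
    amplitudes: dict[str, float],
    seed: int,
    base_patterns: dict[str, np.ndarray] | None = None,
    perturbation: float = 0.0,
) -> dict[str, np.ndarray]:
    """Unit-norm random pattern per quantity, scaled by its amplitude.

    With ``base_patterns`` given, returns base + perturbation * amp * (unit
    random direction) — the subject-level model around a group pattern.
    """
    rng = rng_for(seed, "patterns")
    out: dict[str, np.ndarray] = {}
    for q in QUANTITIES:
        amp = float(amplitudes.get(q, 0.0))
        direction = rng.normal(size=n_voxels)
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 0 else direction
        if base_patterns is None:
            out[q] = amp * direction
        else:
            out[q] = base_patterns[q] + perturbation * amp * direction
    return out


def render_bold(
    amplitudes: dict[str, np.ndarray],
    encoding_patterns: dict[str, np.ndarray],
    geometry: MaskGeometry,
    tr: float = 2.0,
    noise_sd: float = 0.5,
    drift_order: int = 2,
    drift_sd: float = 0.25,
    seed: int = 0,
) -> BoldRun:
    """Forward-model a BOLD run from neural amplitude time courses.

    Per voxel i: ``signal_i(t) = sum_q pattern_q[i] * (h * amp_q)(t)`` where
    ``h`` is the canonical HRF sampled at TR, plus white Gaussian noise and
    random Legendre drift (orders 1..drift_order), then mean-centered per
    voxel.
    """
    lengths = {np.asarray(v).shape[0] for v in amplitudes.values()}
    if len(lengths) != 1:
        raise ValueError("amplitude time courses have mismatched lengths")
    n_volumes = lengths.pop()
    n_voxels = geometry.n_voxels
    signal = np.zeros((n_voxels, n_volumes))
    for q, amp in amplitudes.items():
        if q not in encoding_patterns:
            raise KeyError(f"no encoding pattern for quantity {q!r}")
        pattern = np.asarray(encoding_patterns[q], dtype=float)
        if pattern.shape[0] != n_voxels:
            raise ValueError("pattern voxel dimension does not match mask")
        signal += np.outer(pattern, convolve_amplitudes(amp, tr))

    rng = rng_for(seed, "bold-noise")
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    if drift_order > 0 and drift_sd > 0:
        t = np.linspace(-1.0, 1.0, n_volumes)
        basis = np.column_stack(
            [legendre.legval(t, np.eye(drift_order + 1)[k]) for k in range(1, drift_order + 1)]
        )
        coefs = rng.normal(0.0, drift_sd, size=(n_voxels, drift_order))
        signal = signal + coefs @ basis.T
    signal = signal - signal.mean(axis=1, keepdims=True)
    return BoldRun(signal, tr, geometry)


# -- cohort ---------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults emulate the real study design at desk scale: 2 s stimuli with
    2-6 s ITIs, one resting run at TR = 2 s, light-damped slow latent
    oscillation, and derivative encodings stronger than state encodings.
    """

    n_subjects: int = 12
    grid_shape: tuple[int, int, int] = (6, 6, 6)
    mask_radius: float | None = None
    n_trials: int = 40
    stim_duration: float = 2.0
    iti_range: tuple[float, float] = (2.0, 6.0)
    rest_volumes: int = 120
    tr: float = 2.0
    dynamics: LatentDynamicsParams = field(default_factory=LatentDynamicsParams)
    pattern_amplitudes: dict[str, float] = field(
        default_factory=lambda: {
            "v": 1.0, "a": 1.0, "dv": 3.0, "da": 3.0, "d2v": 8.0, "d2a": 8.0
        }
    )
    bold_noise_sd: float = 0.5
    drift_order: int = 2
    drift_sd: float = 0.25
    subject_perturbation: float = 0.2

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("need >= 2 subjects (>= 1 training subject per hold-out)")

    def with_zero_patterns(self) -> "CohortConfig":
        """Signal-free variant: all encoding amplitudes zero."""
        return replace(self, pattern_amplitudes={q: 0.0 for q in QUANTITIES})


def subject_ids(n_subjects: int) -> list[str]:
    return [f"sub-{i + 1:02d}" for i in range(n_subjects)]


def task_run_volumes(events: Sequence[TrialEvent], tr: float, tail_s: float = 16.0) -> int:
    last = max(e.onset + e.duration for e in events)
    return int(np.ceil((last + tail_s) / tr))


def trial_amplitude_course(
    events: Sequence[TrialEvent], n_volumes: int, tr: float
) -> dict[str, np.ndarray]:
    """State-pattern neural drive of a task run: (score - 5)/4 per trial."""
    av = np.zeros(n_volumes)
    aa = np.zeros(n_volumes)
    for e in events:
        box = boxcar(e.onset, e.duration, n_volumes, tr)
        av += box * (e.valence - 5.0) / 4.0
        aa += box * (e.arousal - 5.0) / 4.0
    return {"v": av, "a": aa}


def generate_cohort(out_dir, config: CohortConfig, seed: int) -> Path:
    """Write a BIDS-like synthetic cohort to disk.

    Layout::

        out_dir/
          mask.nii.gz              shared gray-matter mask
          group_truth.npz          group-level encoding patterns
          sub-01/
            task_bold.nii.gz       affect-induction run (4-D)
            task_events.tsv        onset/duration/stimulus_id/valence/arousal
            rest_bold.nii.gz       resting run (4-D)
            ground_truth.npz       latent series, derivatives, subject patterns
          ...

    All content is a pure function of (config, seed).
    """
    out = ensure_dir(out_dir)
    geometry = ball_mask(config.grid_shape, config.mask_radius)
    save_mask(out / "mask.nii.gz", geometry)

    group_patterns = generate_encoding_patterns(
        geometry.n_voxels, config.pattern_amplitudes, seed=seed
    )
    np.savez(
        out / "group_truth.npz",
        **{f"pattern_{q}": group_patterns[q] for q in QUANTITIES},
    )

    for s, sid in enumerate(subject_ids(config.n_subjects)):
        sub_dir = ensure_dir(out / sid)
        patterns = generate_encoding_patterns(
            geometry.n_voxels,
            config.pattern_amplitudes,
            seed=rng_for(seed, sid, "pattern").integers(2**31),
            base_patterns=group_patterns,
            perturbation=config.subject_perturbation,
        )

        # task run
        events = generate_task_events(
            config.n_trials,
            config.stim_duration,
            config.iti_range,
            seed=rng_for(seed, sid, "events").integers(2**31),
        )
        n_task_vol = task_run_volumes(events, config.tr)
        task_amp = trial_amplitude_course(events, n_task_vol, config.tr)
        task_run = render_bold(
            task_amp,
            patterns,
            geometry,
            tr=config.tr,
            noise_sd=config.bold_noise_sd,
            drift_order=config.drift_order,
            drift_sd=config.drift_sd,
            seed=rng_for(seed, sid, "task-bold").integers(2**31),
        )
        save_bold_run(sub_dir / "task_bold.nii.gz", task_run)
        write_events(sub_dir / "task_events.tsv", events)

        # resting run driven by the latent oscillator and its derivatives
        truth = generate_latent_trajectory(
            config.dynamics,
            config.rest_volumes,
            seed=rng_for(seed, sid, "latent").integers(2**31),
        )
        rest_amp = {
            "v": truth.latent[:, 0],
            "a": truth.latent[:, 1],
            "dv": truth.latent_d1[:, 0],
            "da": truth.latent_d1[:, 1],
            "d2v": truth.latent_d2[:, 0],
            "d2a": truth.latent_d2[:, 1],
        }
        rest_run = render_bold(
            rest_amp,
            patterns,
            geometry,
            tr=config.tr,
            noise_sd=config.bold_noise_sd,
            drift_order=config.drift_order,
            drift_sd=config.drift_sd,
            seed=rng_for(seed, sid, "rest-bold").integers(2**31),
        )
        save_bold_run(sub_dir / "rest_bold.nii.gz", rest_run)
        np.savez(
            sub_dir / "ground_truth.npz",
            latent=truth.latent,
            latent_d1=truth.latent_d1,
            latent_d2=truth.latent_d2,
            noise_sd=np.array([config.bold_noise_sd]),
            **{f"pattern_{q}": patterns[q] for q in QUANTITIES},
        )
    return out
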