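"""Shared fixtures: an in-memory reference cohort used across the suite.

The reference cohort is built once per session at the package's default
study conditions (20 subjects, ~136-voxel ball mask, 40 induction trials,
120 resting volumes) and feeds the decoder-recovery, dynamics-recovery and
simulation tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from affectdyn._seeds import rng_for
from affectdyn.betaseries import lss_solve
from affectdyn.decoders import binarize_scores, fit_classifier
from affectdyn.dynamics import loso_derivative_predictions
from affectdyn.restdecode import decode_resting_run, plan_self_task
from affectdyn.synth import (
    CohortConfig,
    ball_mask,
    generate_encoding_patterns,
    generate_latent_trajectory,
    generate_task_events,
    render_bold,
    subject_ids,
    task_run_volumes,
    trial_amplitude_course,
)

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")

DIMS = ("valence", "arousal")

REFERENCE_SEED = 7
REFERENCE_N_SUBJECTS = 20


def build_subject(config: CohortConfig, geometry, group_patterns, sid: str, seed: int):
    """One synthetic subject: patterns, task betas, state models, rest run."""
    patterns = generate_encoding_patterns(
        geometry.n_voxels,
        config.pattern_amplitudes,
        seed=rng_for(seed, sid, "pattern").integers(2**31),
        base_patterns=group_patterns,
        perturbation=config.subject_perturbation,
    )
    events = generate_task_events(
        config.n_trials, seed=rng_for(seed, sid, "events").integers(2**31)
    )
    n_vol = task_run_volumes(events, config.tr)
    task_run = render_bold(
        trial_amplitude_course(events, n_vol, config.tr),
        patterns,
        geometry,
        tr=config.tr,
        noise_sd=config.bold_noise_sd,
        seed=rng_for(seed, sid, "task-bold").integers(2**31),
    )
    betas = lss_solve(task_run, events, drift_order=2)
    models = {}
    for dim in DIMS:
        scores = np.array(
            [e.valence if dim == "valence" else e.arousal for e in events]
        )
        models[dim] = fit_classifier(
            betas.betas,
            binarize_scores(scores, dim),
            training_meta={"subject_id": sid},
        )
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
        seed=rng_for(seed, sid, "rest-bold").integers(2**31),
    )
    return {
        "patterns": patterns,
        "events": events,
        "betas": betas,
        "models": models,
        "truth": truth,
        "rest": rest_run,
    }


def build_cohort(config: CohortConfig, n_subjects: int, seed: int):
    geometry = ball_mask(config.grid_shape, config.mask_radius)
    group_patterns = generate_encoding_patterns(
        geometry.n_voxels, config.pattern_amplitudes, seed=seed
    )
    subjects = {
        sid: build_subject(config, geometry, group_patterns, sid, seed)
        for sid in subject_ids(n_subjects)
    }
    return {
        "config": config,
        "geometry": geometry,
        "group_patterns": group_patterns,
        "subjects": subjects,
        "seed": seed,
    }


@pytest.fixture(scope="session")
def reference_cohort():
    """20 synthetic subjects at the default (reference) study conditions."""
    return build_cohort(CohortConfig(), REFERENCE_N_SUBJECTS, REFERENCE_SEED)


@pytest.fixture(scope="session")
def reference_decodes(reference_cohort):
    """Out-of-sample resting decodings for every subject of the cohort."""
    config = reference_cohort["config"]
    subjects = reference_cohort["subjects"]
    seed = reference_cohort["seed"]
    decodes = {}
    for sid, sub in subjects.items():
        plan = plan_self_task(
            config.rest_volumes,
            tr=config.tr,
            n_stimuli=100,
            n_iterations=30,
            seed=rng_for(seed, sid, "plan").integers(2**31),
        )
        training = {
            dim: [subjects[o]["models"][dim] for o in subjects if o != sid]
            for dim in DIMS
        }
        decodes[sid] = decode_resting_run(
            sub["rest"], plan, training, hold_out_subject=sid
        )
    return decodes


@pytest.fixture(scope="session")
def reference_loso(reference_decodes):
    """Leave-one-subject-out decoded derivatives across the cohort."""
    return loso_derivative_predictions(reference_decodes)


@pytest.fixture(scope="session")
def reference_simulation_inputs(reference_cohort, reference_decodes, reference_loso):
    """Per-subject decoded series + decoded derivatives for the simulator."""
    config = reference_cohort["config"]
    table = reference_loso
    subject_series = {}
    for sid, decode in reference_decodes.items():
        per = {}
        for dim in DIMS:
            sub = table[(table["subject"] == sid) & (table["dimension"] == dim)]
            d1 = np.full(config.rest_volumes, np.nan)
            d2 = np.full(config.rest_volumes, np.nan)
            s1, s2 = sub[sub["order"] == 1], sub[sub["order"] == 2]
            d1[s1["volume"].to_numpy()] = s1["decoded"].to_numpy()
            d2[s2["volume"].to_numpy()] = s2["decoded"].to_numpy()
            per[dim] = {"value": decode.series[dim].value, "d1": d1, "d2": d2}
        subject_series[sid] = per
    return subject_series
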