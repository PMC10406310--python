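"""End-to-end orchestration of the resting affect dynamics pipeline.

Stages (each reads its inputs from disk and writes a manifest):

    synth         synthetic cohort on disk
    betas         task-trial beta series per subject (LSS)
    fit-decoders  state classifiers + balanced LOOCV report
    decode-rest   out-of-sample ensemble decoding of resting runs
    dynamics      derivative decoders + leave-one-subject-out predictions
    simulate      closed-loop vs surrogate error profile + RMSE growth
    encode        Haufe encoding maps with permutation/cluster testing
    validate      mixed-model validation of derivative decodings

``run_stage("all", ...)`` runs them in order.  Every stochastic operation
draws its seed deterministically from (master seed, subject, stage), so a
rerun with the same config and seed reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from ._seeds import rng_for
from . import io
from .betaseries import lss_solve
from .config import PipelineConfig
from .decoders import binarize_scores, fit_classifier, loocv_balanced_accuracy
from .dynamics import (
    derivative_series,
    fit_derivative_decoder,
    loso_derivative_predictions,
)
from .encoding import build_encoding_map, cluster_table, haufe_transform, permutation_null, write_stat_map
from .restdecode import decode_resting_run, plan_self_task
from .simulate import error_profile, rmse_growth
from .groupstats import group_fixed_effect
from .synth import QUANTITY_OF, generate_cohort, subject_ids
from .types import BoldRun

logger = logging.getLogger("affectdyn")

STAGES = (
    "synth",
    "betas",
    "fit-decoders",
    "decode-rest",
    "dynamics",
    "simulate",
    "encode",
    "validate",
)

DIMS = ("valence", "arousal")


class MissingUpstreamError(RuntimeError):
    def __init__(self, missing: Path, stage_to_run: str):
        super().__init__(
            f"missing upstream artifact {missing}; run stage {stage_to_run!r} first"
        )


def _require(path: Path, producer: str) -> Path:
    if not Path(path).exists():
        raise MissingUpstreamError(Path(path), producer)
    return Path(path)


def _write_manifest(out: Path, stage: str, config: PipelineConfig,
                    inputs: list, outputs: list, t0: float) -> None:
    manifest = {
        "stage": stage,
        "seed": config.master_seed,
        "config_hash": config.config_hash(),
        "inputs": sorted(str(p) for p in inputs),
        "outputs": sorted(str(p) for p in outputs),
        "runtime_s": round(time.time() - t0, 3),
    }
    with open(out / f"manifest_{stage.replace('-', '_')}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _load_cohort_geometry(out: Path):
    mask = _require(out / "cohort" / "mask.nii.gz", "synth")
    return io.load_mask(mask)


def _sids(config: PipelineConfig) -> list[str]:
    return subject_ids(config.cohort.n_subjects)


# -- stages ---------------------------------------------------------------


def stage_synth(config: PipelineConfig, out: Path) -> list[Path]:
    cohort_dir = generate_cohort(out / "cohort", config.cohort, seed=config.master_seed)
    return [cohort_dir]


def stage_betas(config: PipelineConfig, out: Path) -> list[Path]:
    geometry = _load_cohort_geometry(out)
    beta_dir = io.ensure_dir(out / "betas")
    outputs = []
    for sid in _sids(config):
        run = io.load_bold_run(
            _require(out / "cohort" / sid / "task_bold.nii.gz", "synth"), geometry
        )
        events = io.read_events(_require(out / "cohort" / sid / "task_events.tsv", "synth"))
        betas = lss_solve(run, events, drift_order=config.drift_order)
        io.save_beta_series(beta_dir / f"{sid}_betas.nii.gz", betas.betas, geometry)
        io.write_table(
            beta_dir / f"{sid}_trials.tsv",
            pd.DataFrame({"trial": betas.trial_index}),
        )
        outputs += [beta_dir / f"{sid}_betas.nii.gz", beta_dir / f"{sid}_trials.tsv"]
        logger.info("betas: %s (%d trials)", sid, betas.betas.shape[0])
    return outputs


def stage_fit_decoders(config: PipelineConfig, out: Path) -> list[Path]:
    dec_dir = io.ensure_dir(out / "decoders")
    outputs = []
    cv_rows = []
    geometry = _load_cohort_geometry(out)
    for sid in _sids(config):
        features = io.load_beta_series(
            _require(out / "betas" / f"{sid}_betas.nii.gz", "betas"), geometry
        )
        events = io.read_events(out / "cohort" / sid / "task_events.tsv")
        scores = {
            "valence": np.array([e.valence for e in events]),
            "arousal": np.array([e.arousal for e in events]),
        }
        for dim in DIMS:
            labels = binarize_scores(scores[dim], dimension=dim)
            model = fit_classifier(
                features, labels, training_meta={"subject_id": sid, "seed": config.master_seed}
            )
            path = dec_dir / f"{sid}_{dim}_state.npz"
            io.save_decoder(path, model)
            outputs.append(path)
            cv = loocv_balanced_accuracy(
                features,
                labels,
                n_resamples=config.cv_resamples,
                seed=rng_for(config.master_seed, sid, dim, "loocv").integers(2**31),
            )
            cv_rows.append((sid, dim, cv.accuracy, cv.n_resamples, cv.null_rate))
            logger.info("fit-decoders: %s %s LOOCV accuracy %.3f", sid, dim, cv.accuracy)
    report = pd.DataFrame(
        cv_rows, columns=["subject", "dimension", "accuracy", "n_resamples", "null_rate"]
    )
    io.write_table(dec_dir / "cv_report.tsv", report)
    outputs.append(dec_dir / "cv_report.tsv")
    return outputs


def _load_state_models(out: Path, sids: list[str]) -> dict[str, dict[str, object]]:
    models: dict[str, dict[str, object]] = {d: {} for d in DIMS}
    for sid in sids:
        for dim in DIMS:
            path = _require(out / "decoders" / f"{sid}_{dim}_state.npz", "fit-decoders")
            models[dim][sid] = io.load_decoder(path)
    return models


def stage_decode_rest(config: PipelineConfig, out: Path) -> list[Path]:
    geometry = _load_cohort_geometry(out)
    sids = _sids(config)
    models = _load_state_models(out, sids)
    rest_dir = io.ensure_dir(out / "rest")
    outputs = []
    for sid in sids:
        run = io.load_bold_run(
            _require(out / "cohort" / sid / "rest_bold.nii.gz", "synth"), geometry
        )
        plan = plan_self_task(
            run.n_volumes,
            tr=run.tr,
            n_stimuli=config.n_stimuli,
            n_iterations=config.n_iterations,
            seed=rng_for(config.master_seed, sid, "self-task").integers(2**31),
        )
        training = {
            dim: [models[dim][o] for o in sids if o != sid] for dim in DIMS
        }
        decode = decode_resting_run(
            run,
            plan,
            training,
            hold_out_subject=sid,
            drift_order=config.drift_order,
            outlier_alpha=config.outlier_alpha,
        )
        for dim in DIMS:
            ser = decode.series[dim]
            table = pd.DataFrame(
                {
                    "volume": np.arange(run.n_volumes),
                    "time_s": run.volume_times,
                    "value": ser.value,
                    "ci_low": ser.ci_low,
                    "ci_high": ser.ci_high,
                    "n": ser.n_samples,
                    "outlier_flag": ser.outlier.astype(int),
                }
            )
            path = rest_dir / f"{sid}_{dim}.tsv"
            io.write_table(path, table)
            outputs.append(path)
        np.savez(rest_dir / f"{sid}_features.npz", features=decode.features)
        outputs.append(rest_dir / f"{sid}_features.npz")
        with open(rest_dir / f"{sid}_plan.json", "w") as fh:
            json.dump(
                {
                    "seed": int(plan.seed),
                    "n_stimuli_per_iter": int(plan.n_stimuli_per_iter),
                    "iterations": [list(map(float, it)) for it in plan.iterations],
                },
                fh, sort_keys=True,
            )
        outputs.append(rest_dir / f"{sid}_plan.json")
        logger.info("decode-rest: %s done", sid)
    return outputs


def _load_decodes(out: Path, sids: list[str]):
    """Reconstruct per-subject decodes (series + features) from disk."""
    decodes = {}
    for sid in sids:
        series = {}
        for dim in DIMS:
            table = io.read_table(_require(out / "rest" / f"{sid}_{dim}.tsv", "decode-rest"))
            series[dim] = SimpleNamespace(value=table["value"].to_numpy(dtype=float))
        arc = np.load(_require(out / "rest" / f"{sid}_features.npz", "decode-rest"))
        decodes[sid] = SimpleNamespace(series=series, features=arc["features"])
    return decodes


def stage_dynamics(config: PipelineConfig, out: Path) -> list[Path]:
    sids = _sids(config)
    decodes = _load_decodes(out, sids)
    dyn_dir = io.ensure_dir(out / "dynamics")
    outputs = []
    # per-subject derivative decoders, serialized for the encoding stage
    for sid in sids:
        decode = decodes[sid]
        for dim in DIMS:
            deriv = derivative_series(decode.series[dim].value, dim)
            for order, target_series in ((1, deriv.d1), (2, deriv.d2)):
                model = fit_derivative_decoder(
                    decode.features,
                    target_series,
                    target=(dim, order),
                    training_meta={"subject_id": sid},
                )
                path = dyn_dir / f"{sid}_{dim}_d{order}.npz"
                io.save_decoder(path, model)
                outputs.append(path)
    # leave-one-subject-out decoded derivatives
    table = loso_derivative_predictions(decodes)
    for sid in sids:
        for dim in DIMS:
            sub = table[(table["subject"] == sid) & (table["dimension"] == dim)]
            wide = (
                sub.pivot(index="volume", columns="order", values=["true", "decoded"])
                .sort_index()
            )
            frame = pd.DataFrame(
                {
                    "volume": wide.index.to_numpy(),
                    "true_d1": wide[("true", 1)].to_numpy(),
                    "decoded_d1": wide[("decoded", 1)].to_numpy(),
                    "true_d2": wide[("true", 2)].to_numpy(),
                    "decoded_d2": wide[("decoded", 2)].to_numpy(),
                }
            )
            path = dyn_dir / f"{sid}_{dim}_loso.tsv"
            io.write_table(path, frame)
            outputs.append(path)
        logger.info("dynamics: %s LOSO predictions written", sid)
    return outputs


def _load_simulation_inputs(config: PipelineConfig, out: Path):
    sids = _sids(config)
    subject_series = {}
    for sid in sids:
        per_dim = {}
        for dim in DIMS:
            rest = io.read_table(_require(out / "rest" / f"{sid}_{dim}.tsv", "decode-rest"))
            n_vol = len(rest)
            loso = io.read_table(
                _require(out / "dynamics" / f"{sid}_{dim}_loso.tsv", "dynamics")
            )
            d1 = np.full(n_vol, np.nan)
            d2 = np.full(n_vol, np.nan)
            vols = loso["volume"].to_numpy(dtype=int)
            d1[vols] = loso["decoded_d1"].to_numpy(dtype=float)
            d2[vols] = loso["decoded_d2"].to_numpy(dtype=float)
            per_dim[dim] = {
                "value": rest["value"].to_numpy(dtype=float),
                "d1": d1,
                "d2": d2,
            }
        subject_series[sid] = per_dim
    return subject_series


def stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    subject_series = _load_simulation_inputs(config, out)
    sim_dir = io.ensure_dir(out / "simulate")
    profile = error_profile(
        subject_series,
        k_max=config.k_max,
        n_iterations=config.n_sim_iterations,
        seed=rng_for(config.master_seed, "simulate").integers(2**31),
    )
    io.write_table(sim_dir / "error_profile.tsv", profile.per_subject)
    io.write_table(sim_dir / "group_tests.tsv", profile.group)
    outputs = [sim_dir / "error_profile.tsv", sim_dir / "group_tests.tsv"]

    growth_rows = []
    summary_rows = []
    for dim in DIMS:
        sub = profile.per_subject[profile.per_subject["dimension"] == dim]
        rmse_table = sub.rename(columns={"rmse_d1_true": "rmse"})[
            ["subject", "step", "rmse"]
        ]
        per_subject, summary = rmse_growth(rmse_table)
        per_subject = per_subject.assign(dimension=dim)
        growth_rows.append(per_subject)
        summary_rows.append(
            (
                dim,
                summary["mean_slope"],
                summary["ci95"][0],
                summary["ci95"][1],
                summary["t"],
                summary["p"],
                summary["n"],
            )
        )
    io.write_table(sim_dir / "rmse_growth.tsv", pd.concat(growth_rows, ignore_index=True))
    io.write_table(
        sim_dir / "rmse_growth_summary.tsv",
        pd.DataFrame(
            summary_rows,
            columns=["dimension", "mean_slope", "ci_low", "ci_high", "t", "p", "n"],
        ),
    )
    outputs += [sim_dir / "rmse_growth.tsv", sim_dir / "rmse_growth_summary.tsv"]
    return outputs


def stage_encode(config: PipelineConfig, out: Path) -> list[Path]:
    geometry = _load_cohort_geometry(out)
    sids = _sids(config)
    enc_dir = io.ensure_dir(out / "encode")
    outputs = []

    # assemble per-target subject features, targets and fitted models
    decodes = _load_decodes(out, sids)
    for dim in DIMS:
        for order in (0, 1, 2):
            quantity = QUANTITY_OF[(dim, order)]
            feats, targs, maps = [], [], []
            for sid in sids:
                if order == 0:
                    X = io.load_beta_series(
                        _require(out / "betas" / f"{sid}_betas.nii.gz", "betas"),
                        geometry,
                    )
                    events = io.read_events(out / "cohort" / sid / "task_events.tsv")
                    scores = np.array(
                        [e.valence if dim == "valence" else e.arousal for e in events]
                    )
                    y = binarize_scores(scores, dimension=dim).labels.astype(float)
                    model = io.load_decoder(
                        _require(out / "decoders" / f"{sid}_{dim}_state.npz", "fit-decoders")
                    )
                else:
                    decode = decodes[sid]
                    deriv = derivative_series(decode.series[dim].value, dim)
                    y_full = deriv.d1 if order == 1 else deriv.d2
                    ok = np.isfinite(y_full) & np.isfinite(decode.features).all(axis=1)
                    X = decode.features[ok]
                    y = y_full[ok]
                    model = io.load_decoder(
                        _require(out / "dynamics" / f"{sid}_{dim}_d{order}.npz", "dynamics")
                    )
                feats.append(X)
                targs.append(y)
                maps.append(haufe_transform(X, model))

            if order == 0:
                def fit_fn(X, y, _dim=dim):
                    from .decoders import AffectClassLabels

                    labels = AffectClassLabels(y.astype(int), y.astype(float), _dim)
                    return fit_classifier(X, labels)
            else:
                def fit_fn(X, y, _dim=dim, _order=order):
                    return fit_derivative_decoder(X, y, target=(_dim, _order))

            null = permutation_null(
                feats,
                targs,
                fit_fn,
                n_perm=config.n_perm,
                seed=rng_for(config.master_seed, "encode", quantity).integers(2**31),
            )
            emap = build_encoding_map(
                np.asarray(maps),
                null,
                geometry,
                target=(dim, order),
                alpha=config.alpha,
                min_cluster=config.min_cluster,
            )
            tmap_path = enc_dir / f"{quantity}_tmap.nii.gz"
            write_stat_map(emap, tmap_path)
            stats_path = enc_dir / f"{quantity}_voxels.tsv"
            io.write_table(
                stats_path,
                pd.DataFrame(
                    {
                        "voxel": np.arange(geometry.n_voxels),
                        "mean_encoding": emap.mean,
                        "t": emap.t,
                        "p": emap.p,
                        "cluster": emap.cluster_labels,
                    }
                ),
            )
            labels3d = geometry.to_volume(emap.cluster_labels.astype(float)).astype(int)
            t3d = geometry.to_volume(np.where(np.isfinite(emap.t), emap.t, 0.0))
            clusters_path = enc_dir / f"{quantity}_clusters.tsv"
            io.write_table(clusters_path, cluster_table(labels3d, t3d))
            outputs += [tmap_path, stats_path, clusters_path]
            logger.info(
                "encode: %s -> %d surviving cluster(s)",
                quantity,
                int(emap.cluster_labels.max()),
            )
    return outputs


def stage_validate(config: PipelineConfig, out: Path) -> list[Path]:
    sids = _sids(config)
    val_dir = io.ensure_dir(out / "validate")
    report_rows = []
    per_sub_frames = []
    long_frames = []
    for dim in DIMS:
        frames = []
        for sid in sids:
            loso = io.read_table(
                _require(out / "dynamics" / f"{sid}_{dim}_loso.tsv", "dynamics")
            )
            frames.append(loso.assign(subject=sid))
        pooled = pd.concat(frames, ignore_index=True)
        for order in (1, 2):
            pairs = pd.DataFrame(
                {
                    "subject": pooled["subject"],
                    "true": pooled[f"true_d{order}"],
                    "decoded": pooled[f"decoded_d{order}"],
                }
            )
            pairs = pairs[np.isfinite(pairs["true"]) & np.isfinite(pairs["decoded"])]
            long_frames.append(
                pairs.assign(volume=pooled.loc[pairs.index, "volume"],
                             dimension=dim, order=order)
            )
            fit = group_fixed_effect(pairs, alpha=config.alpha)
            report_rows.append(
                (
                    dim, order, fit.fixed_slope, fit.ci95[0], fit.ci95[1], fit.p,
                    fit.r2_adj, fit.r2_adj_marginal, fit.n_significant,
                    fit.meta["n_subjects"], fit.method,
                )
            )
            per_sub_frames.append(fit.per_subject.assign(dimension=dim, order=order))
            logger.info(
                "validate: %s d%d slope=%.3f p=%.2g (%s)",
                dim, order, fit.fixed_slope, fit.p, fit.method,
            )
    report = pd.DataFrame(
        report_rows,
        columns=[
            "dimension", "order", "fixed_slope", "ci_low", "ci_high", "p",
            "r2_adj", "r2_adj_marginal", "n_significant", "n_subjects", "method",
        ],
    )
    io.write_table(val_dir / "validation_report.tsv", report)
    io.write_table(
        val_dir / "per_subject_validation.tsv",
        pd.concat(per_sub_frames, ignore_index=True),
    )
    long = pd.concat(long_frames, ignore_index=True)[
        ["subject", "dimension", "order", "volume", "true", "decoded"]
    ]
    io.write_table(val_dir / "validation_pairs.tsv", long)
    return [
        val_dir / "validation_report.tsv",
        val_dir / "per_subject_validation.tsv",
        val_dir / "validation_pairs.tsv",
    ]


_STAGE_FN = {
    "synth": stage_synth,
    "betas": stage_betas,
    "fit-decoders": stage_fit_decoders,
    "decode-rest": stage_decode_rest,
    "dynamics": stage_dynamics,
    "simulate": stage_simulate,
    "encode": stage_encode,
    "validate": stage_validate,
}

_STAGE_INPUTS = {
    "synth": [],
    "betas": ["cohort"],
    "fit-decoders": ["betas"],
    "decode-rest": ["decoders"],
    "dynamics": ["rest"],
    "simulate": ["dynamics"],
    "encode": ["dynamics"],
    "validate": ["dynamics"],
}


def run_stage(stage: str, config: PipelineConfig, out_dir) -> list[Path]:
    """Execute one pipeline stage (or ``"all"``); returns output paths."""
    out = io.ensure_dir(out_dir)
    if stage == "all":
        outputs = []
        for s in STAGES:
            outputs += run_stage(s, config, out)
        return outputs
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    t0 = time.time()
    logger.info("stage %s starting", stage)
    outputs = _STAGE_FN[stage](config, out)
    inputs = [out / name for name in _STAGE_INPUTS[stage]]
    _write_manifest(out, stage, config, inputs, outputs, t0)
    logger.info("stage %s finished in %.1fs", stage, time.time() - t0)
    return outputs
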