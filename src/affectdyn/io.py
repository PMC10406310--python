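"""NIfTI, events-table and model serialization helpers.

Volumetric data travel as NIfTI-1 (via nibabel), events and all tabular
outputs as tab-separated text with headers, decoding models as ``.npz``
archives.  Floating-point tables are written with a fixed ``%.10g`` format
so identical pipelines produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BoldRun, LinearDecoder, MaskGeometry

__all__ = [
    "save_mask",
    "load_mask",
    "save_bold_run",
    "load_bold_run",
    "save_beta_series",
    "load_beta_series",
    "write_events",
    "read_events",
    "write_table",
    "read_table",
    "save_decoder",
    "load_decoder",
]

FLOAT_FORMAT = "%.10g"


def _affine(voxel_size_mm: float = 3.0) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= voxel_size_mm
    return aff


def save_mask(path, geometry: MaskGeometry) -> None:
    img = nib.Nifti1Image(geometry.mask_array().astype(np.uint8), _affine())
    nib.save(img, str(path))


def load_mask(path) -> MaskGeometry:
    img = nib.load(str(path))
    return MaskGeometry.from_mask(np.asarray(img.dataobj) > 0)


def save_bold_run(path, run: BoldRun) -> None:
    """Write a masked run as a full 4-D NIfTI (zeros outside the mask)."""
    vol4d = np.zeros(run.geometry.shape + (run.n_volumes,), dtype=np.float64)
    flat = vol4d.reshape(-1, run.n_volumes)
    flat[run.geometry.flat_indices] = run.data
    img = nib.Nifti1Image(vol4d, _affine())
    img.header.set_zooms((3.0, 3.0, 3.0, run.tr))
    nib.save(img, str(path))


def load_bold_run(path, geometry: MaskGeometry, tr: float | None = None) -> BoldRun:
    img = nib.load(str(path))
    data4d = np.asarray(img.dataobj, dtype=np.float64)
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    masked = data4d.reshape(-1, data4d.shape[3])[geometry.flat_indices]
    return BoldRun(masked, tr, geometry)


def save_beta_series(path, betas: np.ndarray, geometry: MaskGeometry) -> None:
    """Write a (trials, voxels) beta series as 4-D NIfTI (trials on dim 4)."""
    betas = np.asarray(betas, dtype=np.float64)
    vol4d = np.zeros(geometry.shape + (betas.shape[0],), dtype=np.float64)
    flat = vol4d.reshape(-1, betas.shape[0])
    flat[geometry.flat_indices] = betas.T
    nib.save(nib.Nifti1Image(vol4d, _affine()), str(path))


def load_beta_series(path, geometry: MaskGeometry) -> np.ndarray:
    img = nib.load(str(path))
    data4d = np.asarray(img.dataobj, dtype=np.float64)
    return data4d.reshape(-1, data4d.shape[3])[geometry.flat_indices].T


# -- events ---------------------------------------------------------------

EVENT_COLUMNS = ["onset", "duration", "stimulus_id", "valence", "arousal"]


def write_events(path, events) -> None:
    rows = [
        (e.onset, e.duration, e.stimulus_id, e.valence, e.arousal) for e in events
    ]
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_events(path):
    from .types import TrialEvent

    df = pd.read_csv(path, sep="\t")
    return [
        TrialEvent(
            onset=float(r.onset),
            duration=float(r.duration),
            stimulus_id=str(r.stimulus_id),
            valence=float(r.valence),
            arousal=float(r.arousal),
        )
        for r in df.itertuples()
    ]


# -- tables ---------------------------------------------------------------


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- decoders -------------------------------------------------------------


def save_decoder(path, model: LinearDecoder) -> None:
    meta_keys = sorted(model.training_meta)
    np.savez(
        str(path),
        weights=model.weights,
        offset=np.array([model.offset]),
        target_dim=np.array([model.target[0]]),
        target_order=np.array([model.target[1]]),
        model_form=np.array([model.model_form]),
        meta_keys=np.array(meta_keys),
        meta_values=np.array([str(model.training_meta[k]) for k in meta_keys]),
    )


def load_decoder(path) -> LinearDecoder:
    with np.load(str(path), allow_pickle=False) as arc:
        meta = dict(zip(arc["meta_keys"].tolist(), arc["meta_values"].tolist()))
        return LinearDecoder(
            weights=arc["weights"],
            offset=float(arc["offset"][0]),
            target=(str(arc["target_dim"][0]), int(arc["target_order"][0])),
            model_form=str(arc["model_form"][0]),
            training_meta=meta,
        )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
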