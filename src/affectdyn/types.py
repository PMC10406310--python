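"""Shared domain containers: mask geometry, BOLD runs, events, decoders.

The package works on masked voxel-by-time matrices rather than full 4-D
arrays; :class:`MaskGeometry` carries the mapping back to the 3-D grid so
cluster statistics and NIfTI output can be reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaskGeometry",
    "BoldRun",
    "TrialEvent",
    "LinearDecoder",
]


@dataclass(frozen=True)
class MaskGeometry:
    """3-D grid shape plus the linear (C-order) indices of in-mask voxels."""

    shape: tuple[int, int, int]
    flat_indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.flat_indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("flat_indices must be 1-D")
        n_grid = int(np.prod(self.shape))
        if idx.size and (idx.min() < 0 or idx.max() >= n_grid):
            raise ValueError("flat_indices out of grid bounds")
        object.__setattr__(self, "flat_indices", idx)

    @property
    def n_voxels(self) -> int:
        return int(self.flat_indices.size)

    @classmethod
    def from_mask(cls, mask3d: np.ndarray) -> "MaskGeometry":
        mask3d = np.asarray(mask3d).astype(bool)
        if mask3d.ndim != 3:
            raise ValueError("mask must be 3-D")
        return cls(tuple(mask3d.shape), np.flatnonzero(mask3d.ravel()))

    def mask_array(self) -> np.ndarray:
        """Dense boolean 3-D mask."""
        flat = np.zeros(int(np.prod(self.shape)), dtype=bool)
        flat[self.flat_indices] = True
        return flat.reshape(self.shape)

    def to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked voxel vector back onto the 3-D grid."""
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != self.n_voxels:
            raise ValueError("vector length does not match mask voxel count")
        flat = np.full(int(np.prod(self.shape)), fill, dtype=float)
        flat[self.flat_indices] = values
        return flat.reshape(self.shape)

    def from_volume(self, vol: np.ndarray) -> np.ndarray:
        vol = np.asarray(vol)
        if vol.shape[:3] != self.shape:
            raise ValueError("volume shape does not match mask grid")
        return vol.reshape(int(np.prod(self.shape)), -1)[self.flat_indices].squeeze()


@dataclass
class BoldRun:
    """Masked voxel x time matrix of percent-signal-change BOLD data."""

    data: np.ndarray  # (voxels, volumes)
    tr: float
    geometry: MaskGeometry

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (voxels, volumes)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.data.shape[0] != self.geometry.n_voxels:
            raise ValueError(
                f"data has {self.data.shape[0]} voxels but mask has "
                f"{self.geometry.n_voxels}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[1])

    @property
    def volume_times(self) -> np.ndarray:
        """Acquisition time of volume i is i * tr (0-based)."""
        return np.arange(self.n_volumes) * self.tr


@dataclass(frozen=True)
class TrialEvent:
    """One stimulus presentation with its normative affect scores."""

    onset: float  # seconds from run start
    duration: float  # seconds
    stimulus_id: str
    valence: float  # Likert 1-9
    arousal: float  # Likert 1-9

    def __post_init__(self):
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for score in (self.valence, self.arousal):
            if not (1.0 <= score <= 9.0):
                raise ValueError("scores must lie in [1, 9]")


@dataclass
class LinearDecoder:
    """Linear decoding model: hyperplane weights + offset.

    ``model_form`` distinguishes SVM classifiers (predictions are signed
    hyperplane distances, normalized by ||w|| so they are geometric-margin
    units) from SVM regressors (predictions are ``w . x + b`` in target
    units).  ``target`` is ``(dimension, order)`` with order 0 for the
    affect state, 1 and 2 for its temporal derivatives.
    """

    weights: np.ndarray
    offset: float
    target: tuple[str, int]
    model_form: str  # "classifier" | "regressor"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.isfinite(self.weights).all() or not np.isfinite(self.offset):
            raise ValueError("decoder parameters must be finite")
        if self.model_form not in ("classifier", "regressor"):
            raise ValueError(f"unknown model_form {self.model_form!r}")

    @property
    def subject_id(self):
        return self.training_meta.get("subject_id")

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Decode one or many brain states.

        Classifiers return the signed geometric distance to the hyperplane;
        regressors return the raw linear prediction.
        """
        x = np.asarray(x, dtype=float)
        raw = x @ self.weights + self.offset
        if self.model_form == "classifier":
            norm = float(np.linalg.norm(self.weights))
            if norm == 0.0:
                raise ValueError("zero-norm weights: hyperplane distance undefined")
            return raw / norm
        return raw
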