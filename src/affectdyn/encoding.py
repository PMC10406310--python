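"""From decoding weights to neural encoding maps.

Decoding weights are not interpretable as activation patterns: a voxel can
receive weight purely to cancel correlated noise.  The Haufe transform
recovers the forward-model pattern ``A = Cov(X) w / Var(w.x)`` — the
activation a unit latent source would produce — which is interpretable
voxelwise.  Group maps are voxelwise means across subjects; significance is
assessed against label-permutation nulls (two-sided rank p with the +1
correction) and surviving voxels are cluster-thresholded under face-wise
(6-neighbor) connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, stats

from ._seeds import rng_for
from .types import LinearDecoder, MaskGeometry

__all__ = [
    "EncodingMap",
    "haufe_transform",
    "group_encoding",
    "permutation_null",
    "voxel_significance",
    "cluster_threshold",
    "cluster_table",
    "write_stat_map",
]


@dataclass
class EncodingMap:
    """Group-level encoding statistics over the masked grid."""

    mean: np.ndarray
    t: np.ndarray
    p: np.ndarray
    cluster_labels: np.ndarray  # per masked voxel, 0 = not in a surviving cluster
    geometry: MaskGeometry
    target: tuple[str, int]
    meta: dict = field(default_factory=dict)


def haufe_transform(features: np.ndarray, model: LinearDecoder) -> np.ndarray:
    """Forward-model activation pattern of a linear decoder.

    ``a = Cov(X) w / Var(w.x)``: the voxel pattern that a unit-variance
    latent source decoded by ``w`` would evoke.  Scaling by the latent
    prediction variance fixes a per-subject convention; group statistics
    are covariant to any common positive rescaling.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (samples >= 2, voxels) feature matrix")
    w = model.weights
    if X.shape[1] != w.shape[0]:
        raise ValueError("feature voxel dimension does not match model")
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    latent = Xc @ w
    var_latent = float(latent @ latent) / (n - 1)
    if var_latent == 0.0:
        raise ValueError("zero latent prediction variance; pattern undefined")
    # Cov(X) w == Xc' (Xc w) / (n-1), without materializing the covariance
    return (Xc.T @ latent) / (n - 1) / var_latent


def group_encoding(subject_maps) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise mean and one-sample t across subject encoding maps.

    Zero-variance voxels get a NaN t-score (flagged rather than infinite).
    """
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need >= 2 subject maps of equal length")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(maps.shape[0])), np.nan)
    return mean, t


def permutation_null(
    subject_features: list[np.ndarray],
    subject_targets: list[np.ndarray],
    fit_fn,
    n_perm: int = 500,
    seed: int = 0,
    max_redraws: int = 100,
) -> np.ndarray:
    """Null distribution of group-mean encoding maps under label permutation.

    Per permutation, each subject's targets are permuted independently, the
    model refit by ``fit_fn(features, permuted_targets)``, and the Haufe
    transform applied; the group mean map is stored.  Degenerate
    permutations (``fit_fn`` raising ValueError, e.g. a single class) are
    redrawn, up to ``max_redraws`` per subject per permutation.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 cannot support any sensible alpha")
    n_sub = len(subject_features)
    if n_sub != len(subject_targets):
        raise ValueError("features/targets subject count mismatch")
    n_vox = subject_features[0].shape[1]
    null = np.empty((n_perm, n_vox))
    for p in range(n_perm):
        maps = np.empty((n_sub, n_vox))
        for s in range(n_sub):
            rng = rng_for(seed, "perm", p, s)
            X, y = subject_features[s], np.asarray(subject_targets[s])
            for attempt in range(max_redraws):
                perm_y = y[rng.permutation(y.shape[0])]
                try:
                    model = fit_fn(X, perm_y)
                    break
                except ValueError:
                    continue
            else:
                raise RuntimeError("could not draw a non-degenerate permutation")
            maps[s] = haufe_transform(X, model)
        null[p] = maps.mean(axis=0)
    return null


def voxel_significance(
    observed: np.ndarray, null_maps: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided permutation rank p per voxel and the suprathreshold mask.

    p = (1 + #{|null| >= |obs|}) / (n_perm + 1), so p is never exactly 0.
    """
    observed = np.asarray(observed, dtype=float)
    null_maps = np.atleast_2d(np.asarray(null_maps, dtype=float))
    if null_maps.shape[0] == 0:
        raise ValueError("empty null distribution")
    n_perm = null_maps.shape[0]
    exceed = (np.abs(null_maps) >= np.abs(observed)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return p, p < alpha


#: shared-face adjacency in 3-D
FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)


def cluster_threshold(mask3d: np.ndarray, min_size: int = 20) -> np.ndarray:
    """Label face-connected clusters, dropping those below ``min_size``.

    Surviving components are relabeled 1..C by decreasing size (ties broken
    by original scan order, so labeling is deterministic).
    """
    mask3d = np.asarray(mask3d).astype(bool)
    if mask3d.ndim != 3:
        raise ValueError("cluster thresholding needs a 3-D mask")
    labels, n_comp = ndimage.label(mask3d, structure=FACE_CONNECTIVITY)
    out = np.zeros_like(labels)
    if n_comp == 0:
        return out
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
    keep = [(int(sz), lab) for lab, sz in enumerate(sizes, start=1) if sz >= min_size]
    keep.sort(key=lambda t: (-t[0], t[1]))
    for new_label, (_, old_label) in enumerate(keep, start=1):
        out[labels == old_label] = new_label
    return out


def cluster_table(cluster_labels3d: np.ndarray, stat3d: np.ndarray) -> pd.DataFrame:
    """Summary of surviving clusters: label, size, peak |stat|, peak index."""
    rows = []
    for lab in np.unique(cluster_labels3d):
        if lab == 0:
            continue
        idx = np.flatnonzero((cluster_labels3d == lab).ravel())
        vals = stat3d.ravel()[idx]
        peak = idx[np.nanargmax(np.abs(vals))]
        rows.append((int(lab), int(idx.size), float(np.nanmax(np.abs(vals))), int(peak)))
    return pd.DataFrame(rows, columns=["label", "size", "peak_abs_t", "peak_flat_index"])


def build_encoding_map(
    subject_maps: np.ndarray,
    null_maps: np.ndarray,
    geometry: MaskGeometry,
    target: tuple[str, int],
    alpha: float = 0.05,
    min_cluster: int = 20,
) -> EncodingMap:
    """Assemble the full group encoding map with significance and clusters."""
    mean, t = group_encoding(subject_maps)
    p, supra = voxel_significance(mean, null_maps, alpha=alpha)
    labels3d = cluster_threshold(geometry.to_volume(supra.astype(float)) > 0, min_cluster)
    labels_masked = geometry.from_volume(labels3d.astype(float)).astype(int)
    return EncodingMap(
        mean=mean,
        t=t,
        p=p,
        cluster_labels=np.atleast_1d(labels_masked),
        geometry=geometry,
        target=target,
        meta={"alpha": alpha, "min_cluster": min_cluster, "n_perm": null_maps.shape[0]},
    )


def write_stat_map(emap: EncodingMap, path) -> None:
    """Write the thresholded t-map: t inside surviving clusters, 0 elsewhere."""
    t_clean = np.where(np.isfinite(emap.t), emap.t, 0.0)
    display = np.where(emap.cluster_labels > 0, t_clean, 0.0)
    vol = emap.geometry.to_volume(display)
    aff = np.eye(4)
    aff[:3, :3] *= 3.0
    nib.save(nib.Nifti1Image(vol, aff), str(path))
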