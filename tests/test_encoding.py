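"""Haufe transform, permutation nulls and face-wise cluster thresholding."""

import numpy as np
import pytest
from scipy import stats

from affectdyn.decoders import binarize_scores, fit_classifier
from affectdyn.encoding import (
    build_encoding_map,
    cluster_threshold,
    group_encoding,
    haufe_transform,
    permutation_null,
    voxel_significance,
    write_stat_map,
)
from affectdyn.synth import ball_mask
from affectdyn.types import LinearDecoder, MaskGeometry


def _decoder(w, form="classifier"):
    return LinearDecoder(np.asarray(w, float), 0.0, ("valence", 0), form)


class TestHaufe:
    def test_single_unit_variance_voxel_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2000, 1))
        x = (x - x.mean()) / x.std(ddof=1)
        a = haufe_transform(x, _decoder([1.0]))
        np.testing.assert_allclose(a, [1.0], atol=1e-6)

    def test_whitened_features_return_weights_up_to_scale(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5000, 4))
        w = np.array([1.0, -2.0, 0.5, 0.0])
        a = haufe_transform(X, _decoder(w))
        a_unit = a / np.linalg.norm(a)
        w_unit = w / np.linalg.norm(w)
        np.testing.assert_allclose(a_unit, w_unit, atol=0.05)

    def test_correlated_noise_recovers_generative_pattern(self):
        # signal s drives voxel 1 only; shared noise n hits both voxels.
        # the optimal decoding weight cancels noise via voxel 2 even though
        # voxel 2 carries no signal; the Haufe pattern must undo this.
        rng = np.random.default_rng(2)
        n = 20000
        s = rng.normal(size=n)
        shared = rng.normal(size=n)
        X = np.column_stack([s + shared, shared])
        w = np.array([1.0, -1.0])  # w.x = s exactly: the perfect decoder
        a = haufe_transform(X, _decoder(w))
        # closed form: Cov = [[2,1],[1,1]], Cov w = [1, 0], Var(w.x) = 1
        np.testing.assert_allclose(a, [1.0, 0.0], atol=0.05)

    def test_zero_variance_prediction_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="variance"):
            haufe_transform(X, _decoder([1.0, 1.0]))


class TestGroupEncoding:
    def test_t_map_matches_statistics_oracle(self):
        rng = np.random.default_rng(3)
        maps = rng.normal(size=(8, 30))
        mean, t = group_encoding(maps)
        t_ref, _ = stats.ttest_1samp(maps, 0.0, axis=0)
        np.testing.assert_allclose(mean, maps.mean(axis=0))
        np.testing.assert_allclose(t, t_ref, atol=1e-10)

    def test_identical_maps_flag_undefined_t(self):
        m = np.tile(np.arange(5.0), (3, 1))
        mean, t = group_encoding(m)
        np.testing.assert_allclose(mean, np.arange(5.0))
        assert np.isnan(t[1:]).all()

    def test_antisymmetric_pair_has_zero_mean(self):
        m = np.array([[1.0, -2.0, 3.0], [-1.0, 2.0, -3.0]])
        mean, _ = group_encoding(m)
        np.testing.assert_allclose(mean, 0.0)


def _classifier_fit_fn(X, y):
    from affectdyn.decoders import AffectClassLabels

    return fit_classifier(X, AffectClassLabels(y.astype(int), y, "valence"))


class TestPermutationNull:
    def _cohort(self, n_sub=4, n_trials=24, n_vox=12, seed=0):
        rng = np.random.default_rng(seed)
        feats = [rng.normal(size=(n_trials, n_vox)) for _ in range(n_sub)]
        targs = [
            np.r_[np.ones(n_trials // 2), -np.ones(n_trials // 2)]
            for _ in range(n_sub)
        ]
        return feats, targs

    def test_fixed_seed_null_is_deterministic(self):
        feats, targs = self._cohort()
        a = permutation_null(feats, targs, _classifier_fit_fn, n_perm=20, seed=5)
        b = permutation_null(feats, targs, _classifier_fit_fn, n_perm=20, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_class_counts_preserved_by_permutation(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(10), -np.ones(14)]
        perm = y[rng.permutation(y.size)]
        assert (perm == 1).sum() == 10 and (perm == -1).sum() == 14

    def test_tiny_n_perm_rejected(self):
        feats, targs = self._cohort()
        with pytest.raises(ValueError, match="n_perm"):
            permutation_null(feats, targs, _classifier_fit_fn, n_perm=5, seed=0)


class TestVoxelSignificance:
    def test_rank_formula_extreme_observation(self):
        null = np.random.default_rng(1).normal(size=(500, 3)) * 0.1
        obs = np.array([10.0, 0.0, -10.0])
        p, mask = voxel_significance(obs, null)
        assert p[0] == pytest.approx(1 / 501)
        assert p[2] == pytest.approx(1 / 501)
        assert mask[0] and mask[2] and not mask[1]

    def test_median_observation_is_nonsignificant(self):
        null = np.linspace(-1, 1, 99)[:, None]
        p, _ = voxel_significance(np.array([0.0]), null)
        assert p[0] > 0.5

    def test_agrees_with_brute_force_recount(self):
        rng = np.random.default_rng(2)
        null = rng.normal(size=(99, 20))
        obs = rng.normal(size=20)
        p, _ = voxel_significance(obs, null)
        brute = np.array(
            [
                (1 + sum(abs(null[i, v]) >= abs(obs[v]) for i in range(99))) / 100
                for v in range(20)
            ]
        )
        np.testing.assert_allclose(p, brute)


class TestClusterThreshold:
    def test_solid_block_survives_as_one_cluster(self):
        grid = np.zeros((6, 6, 6), dtype=bool)
        grid[1:4, 1:4, 1:4] = True  # 27 voxels
        labels = cluster_threshold(grid, min_size=20)
        assert labels.max() == 1
        assert (labels > 0).sum() == 27

    def test_isolated_voxel_removed(self):
        grid = np.zeros((5, 5, 5), dtype=bool)
        grid[2, 2, 2] = True
        assert cluster_threshold(grid, min_size=2).max() == 0

    def test_diagonal_touching_19_blobs_both_removed(self):
        # two 19-voxel bars meeting only at a corner: diagonals do not
        # connect under face-wise adjacency, so each stays < 20 and dies
        grid = np.zeros((20, 3, 3), dtype=bool)
        grid[:19, 0, 0] = True
        grid[1:20, 1, 1] = True
        from scipy import ndimage

        labels6, n6 = ndimage.label(grid, ndimage.generate_binary_structure(3, 1))
        assert n6 == 2  # flood-fill oracle: they are separate face-wise
        out = cluster_threshold(grid, min_size=20)
        assert out.max() == 0

    def test_twenty_voxel_block_retained(self):
        grid = np.zeros((20, 4, 4), dtype=bool)
        grid[:20, 0, 0] = True
        out = cluster_threshold(grid, min_size=20)
        assert (out == 1).sum() == 20

    def test_relabeling_invariance_under_axis_permutation(self):
        rng = np.random.default_rng(4)
        grid = rng.random((8, 8, 8)) > 0.7
        a = cluster_threshold(grid, min_size=4)
        b = cluster_threshold(grid.transpose(2, 0, 1), min_size=4)
        sizes_a = sorted(np.bincount(a.ravel())[1:], reverse=True)
        sizes_b = sorted(np.bincount(b.ravel())[1:], reverse=True)
        assert sizes_a == sizes_b


class TestStatMapIo:
    def test_round_trip_and_zero_outside_clusters(self, tmp_path):
        import nibabel as nib

        geom = ball_mask((5, 5, 5))
        rng = np.random.default_rng(5)
        maps = rng.normal(size=(6, geom.n_voxels)) + 1.0
        null = rng.normal(size=(50, geom.n_voxels)) * 0.01
        emap = build_encoding_map(
            maps, null, geom, target=("valence", 1), alpha=0.05, min_cluster=5
        )
        path = tmp_path / "tmap.nii.gz"
        write_stat_map(emap, path)
        vol = np.asarray(nib.load(str(path)).dataobj)
        assert vol.shape == geom.shape
        back = geom.from_volume(vol)
        outside = emap.cluster_labels == 0
        np.testing.assert_allclose(back[outside], 0.0)
        inside = emap.cluster_labels > 0
        np.testing.assert_allclose(back[inside], emap.t[inside], atol=1e-6)
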