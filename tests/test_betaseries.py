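"""Beta-series LSS regression and its GLM oracle."""

import numpy as np
import pytest

from affectdyn.betaseries import (
    drift_basis,
    group_gm_mask,
    hrf_regressor,
    lss_solve,
    nuisance_regress,
)
from affectdyn.hrf import double_gamma_hrf
from affectdyn.synth import ball_mask
from affectdyn.types import BoldRun, TrialEvent


def _event(onset, v=7.0, a=3.0, dur=2.0, sid="s"):
    return TrialEvent(onset=onset, duration=dur, stimulus_id=sid, valence=v, arousal=a)


def _render_run(geom, events, amps, n_vol, tr=2.0, noise=0.0, rng=None):
    """Noiseless (or fixed-noise) run from per-trial amplitudes, one pattern."""
    pattern = np.linspace(0.5, 1.5, geom.n_voxels)
    sig = np.zeros((geom.n_voxels, n_vol))
    for e, a in zip(events, amps):
        sig += np.outer(pattern * a, hrf_regressor([e], n_vol, tr))
    if noise > 0:
        sig = sig + (rng or np.random.default_rng(0)).normal(0, noise, sig.shape)
    return BoldRun(sig - sig.mean(axis=1, keepdims=True), tr, geom), pattern


class TestHrfRegressor:
    def test_empty_event_list_is_zero(self):
        np.testing.assert_array_equal(hrf_regressor([], 20, 2.0), np.zeros(20))

    def test_single_event_proportional_to_kernel(self):
        col = hrf_regressor([_event(0.0)], 30, 2.0)
        h = double_gamma_hrf(2.0)
        np.testing.assert_allclose(col[: h.size], h / np.abs(h).max(), atol=1e-12)
        assert np.abs(col).max() == pytest.approx(1.0)

    def test_linearity_for_distant_events(self):
        n = 60
        both = hrf_regressor([_event(0.0), _event(80.0)], n, 2.0)
        e1 = hrf_regressor([_event(0.0)], n, 2.0)
        e2 = hrf_regressor([_event(80.0)], n, 2.0)
        # shared peak normalization: compare shapes up to the common scale
        np.testing.assert_allclose(
            both / np.abs(both).max(), (e1 + e2) / np.abs(e1 + e2).max(), atol=1e-12
        )

    def test_event_beyond_run_end_warns(self):
        with pytest.warns(UserWarning, match="truncat|after run end"):
            hrf_regressor([_event(39.0)], 20, 2.0)


class TestLssSolve:
    def test_matches_per_trial_glm_when_trials_are_isolated(self):
        # separation beyond the 32 s HRF support + intercept baseline:
        # the aggregate other-trial regressor is then orthogonal to each
        # trial after baseline projection and LSS = per-trial GLM exactly
        geom = ball_mask((3, 3, 3))
        events = [_event(40.0 * i, sid=f"s{i}") for i in range(5)]
        n_vol = 100
        amps = np.array([1.0, -0.5, 2.0, 0.3, -1.2])
        run, pattern = _render_run(geom, events, amps, n_vol)
        betas = lss_solve(run, events, drift_order=0)
        X = np.column_stack(
            [hrf_regressor([e], n_vol, 2.0) for e in events] + [drift_basis(n_vol, 0)]
        )
        glm, *_ = np.linalg.lstsq(X, run.data.T, rcond=None)
        assert np.abs(betas.betas - glm[:5]).max() < 1e-6
        assert np.abs(betas.betas - np.outer(amps, pattern)).max() < 1e-6

    def test_single_event_reduces_to_glm(self):
        geom = ball_mask((3, 3, 3))
        events = [_event(10.0)]
        run, _ = _render_run(geom, events, [1.0], 40)
        betas = lss_solve(run, events, drift_order=1)
        X = np.column_stack([hrf_regressor(events, 40, 2.0), drift_basis(40, 1)])
        glm, *_ = np.linalg.lstsq(X, run.data.T, rcond=None)
        np.testing.assert_allclose(betas.betas[0], glm[0], atol=1e-10)

    def test_doubling_one_amplitude_doubles_its_beta(self):
        geom = ball_mask((3, 3, 3))
        events = [_event(40.0 * i, sid=f"s{i}") for i in range(4)]
        base = np.array([1.0, 1.0, 1.0, 1.0])
        run1, _ = _render_run(geom, events, base, 90)
        run2, _ = _render_run(geom, events, base * [1, 2, 1, 1], 90)
        b1 = lss_solve(run1, events, drift_order=0).betas
        b2 = lss_solve(run2, events, drift_order=0).betas
        np.testing.assert_allclose(b2[1], 2 * b1[1], atol=1e-8)

    def test_shift_equivariance(self):
        # delaying all events and data by m volumes leaves betas unchanged
        geom = ball_mask((3, 3, 3))
        rng = np.random.default_rng(4)
        events = [_event(30.0 * i, sid=f"s{i}") for i in range(3)]
        # all HRF responses die out well before the run end, so delaying
        # events and data together is a pure row permutation of the OLS
        # problem and must leave the betas untouched
        n_vol, m = 80, 5
        run, _ = _render_run(geom, events, [1.0, -1.0, 0.5], n_vol, noise=0.2, rng=rng)
        shifted_events = [
            _event(e.onset + m * 2.0, sid=e.stimulus_id) for e in events
        ]
        run_s = BoldRun(np.roll(run.data, m, axis=1), 2.0, geom)
        b0 = lss_solve(run, events, drift_order=0).betas
        bs = lss_solve(run_s, shifted_events, drift_order=0).betas
        np.testing.assert_allclose(b0, bs, atol=1e-6)

    def test_lss_converges_to_glm_with_spacing(self):
        # on a fixed noise draw the LSS-GLM gap is nonincreasing in spacing
        geom = ball_mask((3, 3, 3))
        gaps = []
        for spacing in (20.0, 36.0, 48.0):
            events = [_event(spacing * i, sid=f"s{i}") for i in range(4)]
            n_vol = int((spacing * 3 + 40) / 2)
            rng = np.random.default_rng(99)
            run, _ = _render_run(
                geom, events, [1.0, -0.5, 0.8, 0.2], n_vol, noise=0.3, rng=rng
            )
            betas = lss_solve(run, events, drift_order=0).betas
            X = np.column_stack(
                [hrf_regressor([e], n_vol, 2.0) for e in events]
                + [drift_basis(n_vol, 0)]
            )
            glm, *_ = np.linalg.lstsq(X, run.data.T, rcond=None)
            gaps.append(np.abs(betas - glm[:4]).max())
        assert gaps[0] >= gaps[1] >= gaps[2]

    def test_rank_deficient_design_is_reported(self):
        geom = ball_mask((3, 3, 3))
        events = [_event(10.0, sid="a"), _event(10.0, sid="b")]  # identical columns
        run, _ = _render_run(geom, [events[0]], [1.0], 40)
        with pytest.raises(np.linalg.LinAlgError, match="rank-deficient"):
            lss_solve(run, events, drift_order=0)


class TestNuisanceRegress:
    def test_own_time_course_zeroes_voxel(self):
        geom = ball_mask((3, 3, 3))
        rng = np.random.default_rng(0)
        data = rng.normal(size=(geom.n_voxels, 40))
        run = BoldRun(data, 2.0, geom)
        out = nuisance_regress(run, data[4][:, None])
        np.testing.assert_allclose(out.data[4], 0.0, atol=1e-10)

    def test_empty_confounds_mean_center(self):
        geom = ball_mask((3, 3, 3))
        data = np.random.default_rng(1).normal(size=(geom.n_voxels, 30))
        out = nuisance_regress(BoldRun(data, 2.0, geom), None)
        np.testing.assert_allclose(out.data, data - data.mean(axis=1, keepdims=True))

    def test_orthogonal_confound_changes_nothing_beyond_mean(self):
        geom = ball_mask((3, 3, 3))
        n = 40
        conf = np.sin(2 * np.pi * np.arange(n) / 8)
        rng = np.random.default_rng(2)
        base = rng.normal(size=(geom.n_voxels, n))
        # orthogonalize data to the confound (and the intercept) first
        X = np.column_stack([np.ones(n), conf])
        proj = X @ np.linalg.lstsq(X, base.T, rcond=None)[0]
        data = base - proj.T
        out = nuisance_regress(BoldRun(data, 2.0, geom), conf[:, None])
        np.testing.assert_allclose(out.data, data, atol=1e-10)


class TestGroupMask:
    def test_half_inclusion_passes_default_threshold(self):
        m1 = np.zeros((3, 3, 3), dtype=bool)
        m1[0, 0, 0] = True
        m2 = np.zeros((3, 3, 3), dtype=bool)
        geom, frac = group_gm_mask([m1, m2])
        assert frac[0, 0, 0] == 0.5
        assert geom.mask_array()[0, 0, 0]  # 0.5 >= 0.5 threshold keeps it

    def test_identical_masks_round_trip(self):
        m = np.random.default_rng(0).random((4, 4, 4)) > 0.5
        geom, _ = group_gm_mask([m, m, m])
        np.testing.assert_array_equal(geom.mask_array(), m)

    def test_threshold_one_is_intersection(self):
        rng = np.random.default_rng(1)
        m1, m2 = rng.random((4, 4, 4)) > 0.3, rng.random((4, 4, 4)) > 0.3
        geom, _ = group_gm_mask([m1, m2], threshold=1.0)
        np.testing.assert_array_equal(geom.mask_array(), m1 & m2)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            group_gm_mask([])
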