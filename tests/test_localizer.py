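"""Incremental GLM vs batch least squares, ROI selection, calibration."""

import numpy as np
import pytest

from nfbloop.errors import CalibrationError, EmptyRoiError, EstimationError
from nfbloop.localizer import (
    VOXEL_CM3,
    GlmState,
    StatMap,
    calibrate_max,
    fit_localizer,
    localizer_design_matrix,
    select_roi,
)
from nfbloop.paradigm import LocalizerDesign
from nfbloop.synthetic import ParticipantModel, simulate_localizer_grid


def batch_t(X, Y, contrast):
    """Reference: batch OLS t-statistics (Y is T x voxels)."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = X.shape[0] - np.linalg.matrix_rank(X)
    sigma2 = np.maximum((resid**2).sum(axis=0) / df, 1e-12)
    cvc = contrast @ np.linalg.solve(X.T @ X, contrast)
    return (contrast @ beta) / np.sqrt(sigma2 * cvc), df


class TestIncrementalGlm:
    def test_intercept_only_recovers_running_mean(self, rng):
        X = np.ones((30, 1))
        state = GlmState(X, (4,))
        data = rng.normal(size=(30, 4))
        for row in data:
            state.update(row)
        assert np.allclose(state.betas()[0], data.mean(axis=0), atol=1e-12)

    def test_matches_batch_ols_oracle(self, rng):
        X = np.column_stack([rng.normal(size=40), np.ones(40), np.linspace(-1, 1, 40)])
        contrast = np.array([1.0, 0.0, 0.0])
        for _ in range(25):
            Y = rng.normal(size=(40, 10))
            state = GlmState(X, (10,))
            for row in Y:
                state.update(row)
            stat = state.t_map(contrast)
            t_ref, df_ref = batch_t(X, Y, contrast)
            assert stat.df == df_ref
            np.testing.assert_allclose(stat.t, t_ref, rtol=1e-8)

    def test_no_volumes_is_an_error(self):
        state = GlmState(np.ones((5, 1)), (2,))
        with pytest.raises(EstimationError):
            state.t_map(np.array([1.0]))

    def test_t_invariant_to_affine_rescaling(self, rng):
        X = localizer_design_matrix(LocalizerDesign(task_blocks=3))
        Y = rng.normal(size=(X.shape[0], 6))
        contrast = np.array([1.0, 0.0, 0.0])

        def run(Ymat):
            s = GlmState(X, (6,))
            for row in Ymat:
                s.update(row)
            return s.t_map(contrast).t

        np.testing.assert_allclose(run(Y), run(3.5 * Y + 17.0), rtol=1e-8)

    def test_perfect_fit_hits_variance_floor_not_infinity(self):
        X = localizer_design_matrix(LocalizerDesign(task_blocks=2))
        Y = np.outer(X[:, 0], [2.0])  # exact multiple of the task regressor
        state = GlmState(X, (1,))
        for row in Y:
            state.update(row)
        t = state.t_map(np.array([1.0, 0.0, 0.0])).t
        assert np.isfinite(t).all() and t[0] > 1e3


class TestSelectRoi:
    def _map(self, t_grid):
        return StatMap(t=np.asarray(t_grid, dtype=float), df=100, contrast=np.array([1.0]))

    def test_single_voxel_roi_size(self):
        t = np.zeros((3, 3, 3))
        t[1, 1, 1] = 8.0
        roi = select_roi(self._map(t), 5.0)
        assert roi.size_voxels == 1
        assert roi.size_cm3 == pytest.approx(0.012)
        assert roi.peak_coord == (1, 1, 1)

    def test_cluster_with_global_peak_wins(self):
        t = np.zeros((5, 5, 1))
        t[0, 0:3, 0] = 6.0  # big cluster, low peak
        t[4, 4, 0] = 9.0  # small cluster, global peak
        roi = select_roi(self._map(t), 5.0)
        assert roi.peak_t == 9.0 and roi.size_voxels == 1

    def test_face_adjacency_not_diagonal(self):
        t = np.zeros((3, 3, 1))
        t[0, 0, 0] = 7.0
        t[1, 1, 0] = 6.0  # diagonal neighbour: separate cluster
        roi = select_roi(self._map(t), 5.0)
        assert roi.size_voxels == 1 and roi.peak_coord == (0, 0, 0)

    def test_empty_threshold_raises(self):
        with pytest.raises(EmptyRoiError):
            select_roi(self._map(np.zeros((2, 2, 2))), 4.0)

    def test_selection_invariant_to_axis_permutation(self, rng):
        t = rng.normal(size=(4, 4, 4))
        t[1, 2, 3] = 10.0
        roi_a = select_roi(self._map(t), 5.0)
        roi_b = select_roi(self._map(np.transpose(t, (2, 1, 0))), 5.0)
        assert roi_a.size_voxels == roi_b.size_voxels
        assert roi_b.peak_coord == tuple(reversed(roi_a.peak_coord))

    def test_planted_block_recovered_exactly(self):
        model = ParticipantModel(gain=4.0, noise_sd=0.3, ar_phi=0.2, drift_slope=0.0)
        design = LocalizerDesign()
        active = [(i, j, k) for i in (1, 2) for j in (1, 2) for k in (1, 2)]
        data, mask = simulate_localizer_grid(model, design, (4, 4, 4), active, rng=0)
        stat = fit_localizer(data, design)
        roi = select_roi(stat, 8.0)
        np.testing.assert_array_equal(roi.as_bool(), mask)
        assert roi.size_cm3 == pytest.approx(VOXEL_CM3 * 8)


class TestCalibrateMax:
    def test_constant_plateaus(self):
        design = LocalizerDesign(task_blocks=3, task_trs=2, rest_trs=2)
        series = np.zeros(design.total_trs)
        t = design.rest_trs
        for _ in range(design.task_blocks):
            series[t : t + design.task_trs] = 4.0
            t += design.task_trs + design.rest_trs
        cal = calibrate_max(series, design)
        assert cal.localizer_max_percent == 4.0

    def test_max_of_block_means(self):
        design = LocalizerDesign(task_blocks=3, task_trs=2, rest_trs=2)
        series = np.zeros(design.total_trs)
        t = design.rest_trs
        for amp in (2.0, 3.0, 4.0):
            series[t : t + design.task_trs] = amp
            t += design.task_trs + design.rest_trs
        assert calibrate_max(series, design).localizer_max_percent == 4.0

    def test_matches_bruteforce_oracle_on_noisy_trace(self, rng):
        design = LocalizerDesign()
        series = rng.normal(1.0, 0.5, design.total_trs)
        cal = calibrate_max(series, design)
        # brute force over blocks
        best = -np.inf
        t = design.rest_trs
        for _ in range(design.task_blocks):
            rest = series[t - design.rest_trs : t].mean()
            task = series[t : t + design.task_trs].mean()
            best = max(best, task - rest)
            t += design.task_trs + design.rest_trs
        assert cal.localizer_max_percent == pytest.approx(best, rel=1e-12)

    def test_non_positive_maximum_is_an_error(self):
        design = LocalizerDesign(task_blocks=2, task_trs=2, rest_trs=2)
        with pytest.raises(CalibrationError):
            calibrate_max(np.zeros(design.total_trs), design)
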