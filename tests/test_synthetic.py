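"""Generators: HRF forward model, behavioural controller, grids, latencies."""

import numpy as np
import pytest

from nfbloop.errors import ConfigurationError
from nfbloop.feedback import CalibrationInfo
from nfbloop.paradigm import BlockSpec, LocalizerDesign, SessionConfig
from nfbloop.synthetic import (
    CohortSpec,
    LatencyModel,
    ParticipantModel,
    double_gamma_hrf,
    effort_trace,
    sample_cohort,
    simulate_bold,
    simulate_latency_log,
    simulate_localizer_grid,
)

QUIET = dict(noise_sd=0.0, drift_slope=0.0)


class TestHrf:
    def test_unit_area(self):
        assert double_gamma_hrf(2.0).sum() == pytest.approx(1.0, abs=1e-12)

    def test_peak_near_six_seconds(self):
        h = double_gamma_hrf(0.5)
        assert 4.0 <= 0.5 * np.argmax(h) <= 7.0


class TestSimulateBold:
    def test_zero_effort_zero_noise_is_identically_zero(self):
        model = ParticipantModel(**QUIET)
        out = simulate_bold(np.zeros(50), model, rng=0)
        assert np.allclose(out, 0.0)

    def test_unit_step_plateau_equals_gain(self):
        model = ParticipantModel(gain=3.7, **QUIET)
        out = simulate_bold(np.ones(60), model, rng=0)
        assert out[-1] == pytest.approx(3.7, abs=1e-9)

    def test_reproducible_per_seed(self):
        model = ParticipantModel(noise_sd=0.3)
        a = simulate_bold(np.ones(40), model, rng=11)
        b = simulate_bold(np.ones(40), model, rng=11)
        c = simulate_bold(np.ones(40), model, rng=12)
        assert np.array_equal(a, b) and not np.array_equal(a, c)

    def test_pure_noise_recovers_ar_coefficient(self):
        # gain = 0: the trace is AR(1); lag-1 autocorrelation ~ phi
        model = ParticipantModel(gain=1e-9, ar_phi=0.5, noise_sd=1.0, drift_slope=0.0)
        out = simulate_bold(np.zeros(6000), model, rng=5)
        r1 = np.corrcoef(out[:-1], out[1:])[0, 1]
        assert r1 == pytest.approx(0.5, abs=0.05)


class TestCohort:
    def test_default_cohort_composition(self):
        models = sample_cohort(CohortSpec(master_seed=1))
        assert len(models) == 9
        assert sum(m.field_strength == "7T" for m in models) == 3
        assert all(1.5 <= m.gain <= 4.5 for m in models)

    def test_degenerate_ranges_give_identical_models(self):
        ranges = {"gain": (2.0, 2.0), "noise_sd": (0.1, 0.1)}
        models = sample_cohort(CohortSpec(master_seed=3, model_ranges=ranges))
        assert all(m.gain == 2.0 and m.noise_sd == 0.1 for m in models)

    def test_seeded_determinism(self):
        a = sample_cohort(CohortSpec(master_seed=9))
        b = sample_cohort(CohortSpec(master_seed=9))
        assert a == b

    def test_empty_range_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortSpec(model_ranges={"gain": (3.0, 2.0)})


class TestEffortTrace:
    def _block(self, modality="cFB", level=2):
        return BlockSpec(0, modality, level, (0, 8), (8, 20), (20, 22))

    def test_zero_tracking_keeps_effort_constant(self):
        model = ParticipantModel(tracking_rate_cFB=0.0, effort_noise_sd=0.0)
        eff = effort_trace(model, self._block(), [10.0] * 12, rng=np.random.default_rng(0))
        assert np.allclose(eff, eff[0])

    def test_feedback_at_target_midpoint_gives_zero_correction(self):
        model = ParticipantModel(tracking_rate_cFB=0.5, effort_noise_sd=0.0)
        # level 2 midpoint on the display scale is 55
        eff = effort_trace(model, self._block(), [55.0] * 12, rng=np.random.default_rng(0))
        assert np.allclose(eff, eff[0])

    def test_below_target_feedback_raises_effort(self):
        model = ParticipantModel(tracking_rate_cFB=0.2, effort_noise_sd=0.0)
        eff = effort_trace(model, self._block(), [20.0] * 12, rng=np.random.default_rng(0))
        assert np.all(np.diff(eff) > 0)

    def test_nofb_gets_no_within_block_correction(self):
        model = ParticipantModel(effort_noise_sd=0.0)
        eff = effort_trace(model, self._block("noFB"), None, n_trs=12,
                           rng=np.random.default_rng(0))
        assert np.allclose(eff, eff[0])


class TestLocalizerGrid:
    def test_ground_truth_mask_and_shapes(self):
        model = ParticipantModel(gain=4.0, noise_sd=0.2)
        design = LocalizerDesign()
        data, mask = simulate_localizer_grid(model, design, (4, 4, 4), [(1, 1, 1)], rng=0)
        assert data.shape == (4, 4, 4, design.total_trs)
        assert mask.sum() == 1 and mask[1, 1, 1]

    def test_active_voxel_carries_task_signal(self):
        model = ParticipantModel(gain=4.0, **QUIET)
        design = LocalizerDesign()
        data, _ = simulate_localizer_grid(model, design, (3, 3, 3), [(0, 0, 0)], rng=0)
        active = data[0, 0, 0]
        inactive = data[2, 2, 2]
        assert active.std() > 0
        assert np.allclose(inactive, 100.0)


class TestLatencyLog:
    def test_degenerate_model_collapses_to_exp_mu(self):
        model = LatencyModel(transfer_log_sigma=0.0, outlier_prob=0.0)
        log = simulate_latency_log(model, 100, seed=0)
        assert np.allclose(log["transfer_ms"], np.exp(model.transfer_log_mu))

    def test_configured_median_recovered(self):
        model = LatencyModel()  # median exp(mu) = 454 ms
        log = simulate_latency_log(model, 12000, seed=1)
        assert np.median(log["transfer_ms"]) == pytest.approx(454, rel=0.05)

    def test_outlier_count_matches_binomial_expectation(self):
        model = LatencyModel(outlier_prob=0.0036)
        n = 12276
        counts = [
            (simulate_latency_log(model, n, seed=s)["transfer_ms"] > 2000).sum()
            for s in range(20)
        ]
        expected = n * 0.0036  # ~44.2
        assert np.mean(counts) == pytest.approx(expected, rel=0.2)

    def test_latencies_non_negative(self):
        log = simulate_latency_log(LatencyModel(outlier_prob=0.01), 5000, seed=2)
        assert (log["transfer_ms"] >= 0).all() and (log["processing_ms"] >= 0).all()


class TestLevelMonotonicity:
    def test_expected_regulation_bold_non_decreasing_in_level(self):
        """Higher cued levels should drive larger regulation %dBOLD on average."""
        from nfbloop.pipeline import simulate_session

        model = ParticipantModel(effort_noise_sd=0.05, init_bias_mean=0.0,
                                 init_bias_sd=0.0, cell_bias_sd=0.0, noise_sd=0.05)
        config = SessionConfig(rng_seed=0)
        _, samples = simulate_session(model, config, seed=0, collect_samples=True)
        by_level = samples.groupby("cued_level")["psc"].mean()
        assert by_level[1] < by_level[2] < by_level[3]
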