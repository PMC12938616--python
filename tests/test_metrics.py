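"""Occupancy, distance-to-range, aggregation and learning deltas."""

import numpy as np
import pandas as pd
import pytest

from nfbloop.feedback import ScoringConfig, classify_block, default_levels
from nfbloop.metrics import (
    aggregate,
    block_metrics,
    distance_to_range,
    learning_delta,
)

LEVELS = default_levels()


class TestDistanceToRange:
    @pytest.mark.parametrize(
        "s,level,expected",
        [
            (35, 1, 0.0),
            (50, 1, 10.0),
            (5, 2, 35.0),
            (5, 1, 5.0),
            (75, 2, 5.0),
            (95, 3, 0.0),  # level 3 upper boundary never contributes distance
            (69, 3, 1.0),
            (40, 1, 0.0),  # exactly at the half-open upper edge: outside, distance 0
        ],
    )
    def test_pointwise(self, s, level, expected):
        d = distance_to_range([s], LEVELS[level])
        assert d[0] == pytest.approx(expected)


class TestBlockMetrics:
    def test_all_in_range(self):
        m = block_metrics([50.0] * 12, 2)
        assert m.occupancy == 1.0 and m.dist_median == 0.0 and m.dist_sd == 0.0

    def test_partial_occupancy(self):
        s = [50.0] * 3 + [10.0] * 9
        m = block_metrics(s, 2)
        assert m.occupancy == pytest.approx(0.25)

    def test_matches_bruteforce_oracle_on_random_blocks(self, rng):
        for _ in range(1000):
            s = rng.uniform(0, 100, 12)
            level = int(rng.integers(1, 4))
            spec = LEVELS[level]
            m = block_metrics(s, level)
            dist = []
            inside = 0
            for v in s:
                if spec.contains(v):
                    inside += 1
                    dist.append(0.0)
                elif v < spec.range_lo:
                    dist.append(spec.range_lo - v)
                elif spec.upper_closed:
                    dist.append(0.0)
                else:
                    dist.append(v - spec.range_hi)
            assert m.occupancy == pytest.approx(inside / 12)
            assert m.dist_median == pytest.approx(float(np.median(dist)))
            assert m.dist_sd == pytest.approx(float(np.std(dist, ddof=1)))

    def test_within_range_success_implies_occupancy_at_least_half(self, rng):
        scoring = ScoringConfig(hit_rule="within_range")
        for _ in range(300):
            s = rng.uniform(0, 100, 12)
            level = int(rng.integers(1, 4))
            if classify_block(s, level, scoring).success:
                assert block_metrics(s, level).occupancy >= 0.5


class TestAggregate:
    def test_overall_rate_from_fixture(self, outcome_fixture):
        pooled = aggregate(outcome_fixture, by=("run_id",))
        total = pooled["n_success"].sum() / pooled["n_blocks"].sum()
        assert round(100 * total, 1) == 44.4
        assert pooled["n_blocks"].sum() == 486

    def test_single_run_rate(self, outcome_fixture):
        per_run = aggregate(outcome_fixture, by=("participant_id", "run_id"))
        row = per_run[(per_run.participant_id == "S05") & (per_run.run_id == "RUN1")]
        assert row["n_success"].item() == 5
        assert round(row["success_rate"].item(), 1) == 18.5

    def test_blocks_per_modality_per_participant(self, outcome_fixture):
        per = aggregate(outcome_fixture, by=("participant_id", "modality"))
        assert (per["n_blocks"] == 18).all()

    def test_invariant_to_row_order(self, outcome_fixture, rng):
        shuffled = outcome_fixture.sample(frac=1.0, random_state=7).reset_index(drop=True)
        a = aggregate(outcome_fixture).reset_index(drop=True)
        b = aggregate(shuffled).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_pooled_rate_is_block_weighted_mean(self, outcome_fixture):
        per = aggregate(outcome_fixture, by=("participant_id",))
        weighted = (per["success_rate"] * per["n_blocks"]).sum() / per["n_blocks"].sum()
        assert weighted == pytest.approx(100 * outcome_fixture["success"].mean())


class TestLearningDelta:
    def test_identical_runs_give_zero_delta(self, outcome_fixture):
        run1 = outcome_fixture[outcome_fixture.run_id == "RUN1"]
        doubled = pd.concat(
            [run1, run1.assign(run_id="RUN2")], ignore_index=True
        )
        cells = aggregate(doubled)
        deltas = learning_delta(cells)
        assert (deltas["delta"] == 0).all()

    def test_group_mean_from_printed_run_means(self, outcome_fixture):
        cells = aggregate(outcome_fixture)
        deltas = learning_delta(cells)
        cfb = deltas[deltas.modality == "cFB"]
        assert round(cfb["run1_value"].mean(), 1) == 39.5
        assert round(cfb["run2_value"].mean(), 1) == 54.3
        assert round(cfb["delta"].mean(), 1) == 14.8

    def test_matches_bruteforce_on_random_table(self, rng):
        rows = []
        for pid in ("A", "B", "C"):
            for run in ("RUN1", "RUN2"):
                for mod in ("cFB", "aFB"):
                    rows.append(
                        {
                            "participant_id": pid,
                            "run_id": run,
                            "modality": mod,
                            "success_rate": float(rng.uniform(0, 100)),
                        }
                    )
        cells = pd.DataFrame(rows)
        deltas = learning_delta(cells)
        for _, r in deltas.iterrows():
            v1 = cells[
                (cells.participant_id == r.participant_id)
                & (cells.modality == r.modality)
                & (cells.run_id == "RUN1")
            ]["success_rate"].item()
            v2 = cells[
                (cells.participant_id == r.participant_id)
                & (cells.modality == r.modality)
                & (cells.run_id == "RUN2")
            ]["success_rate"].item()
            assert r.delta == pytest.approx(v2 - v1)

    def test_participant_missing_a_run_excluded_with_warning(self, outcome_fixture):
        cells = aggregate(outcome_fixture)
        cells = cells[
            ~((cells.participant_id == "S09") & (cells.run_id == "RUN2"))
        ]
        with pytest.warns(UserWarning, match="S09"):
            deltas = learning_delta(cells)
        assert "S09" not in set(deltas.participant_id)
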