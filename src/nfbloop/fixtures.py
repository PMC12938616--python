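"""Deterministic worked-example fixtures.

These synthetic tables mirror the published group-level summary structure
of the emulated study so that the aggregation, learning and latency
operations can be exercised against hand-checkable numbers:

* an outcome table of 9 participants x 2 runs x 27 blocks whose per-cell
  success counts reproduce the group success rates (44.4% overall; cFB
  39.5% -> 54.3% across runs; one 5-success run at 18.5%; one 20-success
  run at 74.1%);
* a latency log of 12,276 volumes (9 participants x [2 x 602 run TRs +
  160 localizer TRs]) with exactly 44 heavy-tail volumes above 2000 ms, all
  at 7T and 41 of them from a single participant, and component means
  pinned at 497.78 ms (transfer) and 296.83 ms (processing);
* a small planted-ROI localizer grid.

Everything is generated programmatically with a fixed internal seed;
regeneration is idempotent.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .paradigm import LocalizerDesign, SessionConfig, make_schedule
from .synthetic import ParticipantModel, simulate_localizer_grid

_FIXTURE_SEED = 20260130

# Successful blocks per (participant, run, modality); 9 blocks per cell.
# Column sums give 32/34/36 (RUN1) and 44/37/33 (RUN2) for cFB/aFB/noFB,
# i.e. 216/486 successes overall, cFB run means 39.5% -> 54.3%, aFB +3.7 pp,
# noFB -3.7 pp; S05 RUN1 totals 5/27 and S03 RUN2 totals 20/27.
SUCCESS_COUNTS = {
    "RUN1": {
        "cFB": (4, 5, 4, 3, 2, 4, 3, 4, 3),
        "aFB": (4, 5, 4, 4, 1, 5, 4, 4, 3),
        "noFB": (5, 4, 5, 4, 2, 5, 4, 4, 3),
    },
    "RUN2": {
        "cFB": (5, 6, 7, 5, 4, 5, 4, 4, 4),
        "aFB": (4, 5, 7, 4, 3, 4, 4, 3, 3),
        "noFB": (4, 4, 6, 4, 3, 4, 3, 3, 2),
    },
}

PARTICIPANTS = tuple(f"S{i:02d}" for i in range(1, 10))
FIELD_OF = {p: ("7T" if p in ("S01", "S02", "S04") else "3T") for p in PARTICIPANTS}

LATENCY_N_VOLUMES = 12276  # 9 x (2 x 602 + 160)
LATENCY_TAIL_COUNTS = {"S02": 41, "S01": 2, "S04": 1}  # all 7T
TRANSFER_MEAN_MS = 497.78
PROCESSING_MEAN_MS = 296.83
TRANSFER_RANGE_MS = (164.0, 12004.0)
PROCESSING_RANGE_MS = (5.0, 478.0)


def make_outcome_fixture(config: SessionConfig | None = None) -> pd.DataFrame:
    """486-row block outcome table realizing the fixed per-cell success counts.

    Block order and cued levels come from the real schedule generator;
    within each (participant, run, modality) cell the successes are
    assigned to the first k blocks in presentation order, which fixes the
    marginal counts without any randomness of its own.
    """
    config = config or SessionConfig(rng_seed=_FIXTURE_SEED)
    rows = []
    for participant in PARTICIPANTS:
        for run in ("RUN1", "RUN2"):
            schedule = make_schedule(config, participant, run)
            seen: dict[str, int] = {}
            for b in schedule.blocks:
                i = seen.get(b.modality, 0)
                seen[b.modality] = i + 1
                n_success = SUCCESS_COUNTS[run][b.modality][PARTICIPANTS.index(participant)]
                success = i < n_success
                rows.append(
                    {
                        "participant_id": participant,
                        "run_id": run,
                        "field_strength": FIELD_OF[participant],
                        "block_index": b.block_index,
                        "modality": b.modality,
                        "cued_level": b.cued_level,
                        "n_hit_trs": 8 if success else 3,
                        "success": success,
                    }
                )
    return pd.DataFrame(rows)


def _pin_mean(values: np.ndarray, free: np.ndarray, target_total: float) -> np.ndarray:
    """Shift the ``free`` subset additively so the overall sum hits the target."""
    shift = (target_total - values.sum()) / free.sum()
    out = values.copy()
    out[free] += shift
    return out


def make_latency_fixture() -> pd.DataFrame:
    """12,276-volume latency log with pinned component means and tail counts."""
    rng = np.random.default_rng(_FIXTURE_SEED)
    per_participant = LATENCY_N_VOLUMES // len(PARTICIPANTS)
    frames = []
    for participant in PARTICIPANTS:
        transfer = rng.lognormal(np.log(454.0), 0.35, per_participant)
        transfer = np.clip(transfer, 170.0, 1900.0)
        processing = np.clip(rng.normal(300.0, 73.0, per_participant), 6.0, 477.0)
        frames.append(
            pd.DataFrame(
                {
                    "volume_index": np.arange(per_participant),
                    "transfer_ms": transfer,
                    "processing_ms": processing,
                    "participant_id": participant,
                    "field_strength": FIELD_OF[participant],
                    "block_context": "regulation",
                }
            )
        )
    log = pd.concat(frames, ignore_index=True)

    # plant the heavy-tail volumes (all 7T, 41 of 44 from one participant)
    tail_rows: list[int] = []
    for participant, count in LATENCY_TAIL_COUNTS.items():
        idx = log.index[log["participant_id"] == participant][:count]
        tail_rows.extend(idx)
    tail_values = np.concatenate(
        [[TRANSFER_RANGE_MS[1]], rng.uniform(2100.0, 9000.0, len(tail_rows) - 1)]
    )
    log.loc[tail_rows, "transfer_ms"] = tail_values

    # pin the printed extremes and the exact component means
    transfer = log["transfer_ms"].to_numpy()
    free = np.ones(len(log), dtype=bool)
    free[tail_rows] = False
    min_row = int(np.argmax(free))  # first non-tail row carries the printed minimum
    transfer[min_row] = TRANSFER_RANGE_MS[0]
    free[min_row] = False
    transfer = _pin_mean(transfer, free, TRANSFER_MEAN_MS * len(log))
    log["transfer_ms"] = transfer

    processing = log["processing_ms"].to_numpy()
    free_p = np.ones(len(log), dtype=bool)
    processing[0], processing[1] = PROCESSING_RANGE_MS
    free_p[:2] = False
    processing = _pin_mean(processing, free_p, PROCESSING_MEAN_MS * len(log))
    log["processing_ms"] = processing
    return log


def make_localizer_fixture() -> tuple[np.ndarray, np.ndarray, LocalizerDesign]:
    """Small planted-ROI grid: 4x4x4 voxels, 2x2x2 active block, low noise."""
    design = LocalizerDesign()
    model = ParticipantModel(gain=4.0, noise_sd=0.3, ar_phi=0.2, drift_slope=0.0)
    active = [(i, j, k) for i in (1, 2) for j in (1, 2) for k in (1, 2)]
    data, mask = simulate_localizer_grid(
        model, design, (4, 4, 4), active, rng=np.random.default_rng(_FIXTURE_SEED)
    )
    return data, mask, design


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_fixtures(out_dir) -> dict:
    """Write all fixture files and a checksum manifest; idempotent."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outcomes = make_outcome_fixture()
    outcomes_path = out_dir / "outcomes_fixture.tsv"
    outcomes.to_csv(outcomes_path, sep="\t", index=False, float_format="%.6f")

    latency = make_latency_fixture()
    latency_path = out_dir / "latency_fixture.tsv"
    latency.to_csv(latency_path, sep="\t", index=False, float_format="%.6f")

    data, mask, design = make_localizer_fixture()
    grid_path = out_dir / "localizer_grid_fixture.npz"
    np.savez_compressed(grid_path, data=data, mask=mask)

    manifest = {
        "files": {p.name: _sha256(p) for p in (outcomes_path, latency_path, grid_path)},
        "n_outcome_rows": int(len(outcomes)),
        "n_latency_rows": int(len(latency)),
        "localizer_design": {
            "task_blocks": design.task_blocks,
            "task_trs": design.task_trs,
            "rest_trs": design.rest_trs,
        },
    }
    manifest_path = out_dir / "fixtures_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
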