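"""Block-design layout of a closed-loop neurofeedback session.

A session consists of two neurofeedback runs.  Each run opens with a short
stabilization baseline and then presents ``blocks_per_run`` trials drawn
without replacement from the fully crossed (feedback modality x cued level)
cell set.  Every trial has three phases laid out back-to-back on the TR
grid: a baseline period, a regulation period during which the participant
up-regulates the target region, and a brief outcome cue.

TR indices are 0-based and all phase windows are half-open ``[start, stop)``
intervals, so the stabilization period plus the union of all block windows
tiles ``[0, total_trs)`` exactly.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

MODALITIES: tuple[str, ...] = ("cFB", "aFB", "noFB")
LEVELS: tuple[int, ...] = (1, 2, 3)


def rng_stream(master_seed: int, *keys: object) -> np.random.Generator:
    """Derive an independent, reproducible generator for a labelled stream.

    The label (e.g. participant and run identifiers) is hashed with CRC-32
    into the seed sequence, so streams are stable across platforms and
    independent of the order in which they are created.
    """
    label = "|".join(str(k) for k in keys)
    crc = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, crc]))


@dataclass(frozen=True)
class SessionConfig:
    """Timing and factorial structure of a neurofeedback session."""

    tr_seconds: float = 2.0
    stabilization_trs: int = 8
    baseline_trs: int = 8
    regulation_trs: int = 12
    outcome_trs: int = 2
    blocks_per_run: int = 27
    runs_per_session: int = 2
    modalities: tuple[str, ...] = MODALITIES
    levels: tuple[int, ...] = LEVELS
    repeats_per_cell: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "stabilization_trs": self.stabilization_trs,
            "baseline_trs": self.baseline_trs,
            "regulation_trs": self.regulation_trs,
            "outcome_trs": self.outcome_trs,
            "blocks_per_run": self.blocks_per_run,
            "runs_per_session": self.runs_per_session,
            "repeats_per_cell": self.repeats_per_cell,
        }
        for name, value in counts.items():
            if name == "stabilization_trs":
                if value < 0:
                    raise ConfigurationError(f"{name} must be non-negative, got {value}")
            elif value <= 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value}")
        if self.tr_seconds <= 0:
            raise ConfigurationError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        n_cells = len(self.modalities) * len(self.levels)
        if self.blocks_per_run != n_cells * self.repeats_per_cell:
            raise ConfigurationError(
                f"blocks_per_run={self.blocks_per_run} != |modalities| x |levels| x "
                f"repeats_per_cell = {n_cells * self.repeats_per_cell}"
            )

    @property
    def block_trs(self) -> int:
        return self.baseline_trs + self.regulation_trs + self.outcome_trs

    @property
    def total_trs(self) -> int:
        return self.stabilization_trs + self.blocks_per_run * self.block_trs


@dataclass
class BlockSpec:
    """One trial: its factorial cell and its TR windows within the run."""

    block_index: int
    modality: str
    cued_level: int
    baseline_window: tuple[int, int] | None = None
    regulation_window: tuple[int, int] | None = None
    outcome_window: tuple[int, int] | None = None


@dataclass
class Schedule:
    """Ordered block list for one run of one participant."""

    participant_id: str
    run_id: str
    blocks: list[BlockSpec] = field(default_factory=list)
    total_trs: int | None = None

    def cell_counts(self) -> dict[tuple[str, int], int]:
        counts: dict[tuple[str, int], int] = {}
        for b in self.blocks:
            key = (b.modality, b.cued_level)
            counts[key] = counts.get(key, 0) + 1
        return counts


@dataclass(frozen=True)
class LocalizerDesign:
    """Alternating rest/task block design of the functional localizer.

    Defaults: ten 5-TR tapping blocks separated (and flanked) by 10-TR
    fixation baselines, at a 2 s TR.
    """

    task_blocks: int = 10
    task_trs: int = 5
    rest_trs: int = 10
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        for name in ("task_blocks", "task_trs", "rest_trs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be > 0")

    @property
    def total_trs(self) -> int:
        return self.task_blocks * self.task_trs + (self.task_blocks + 1) * self.rest_trs


def make_schedule(config: SessionConfig, participant_id: str, run_id: str) -> Schedule:
    """Draw the run's block order: a uniform shuffle of the crossed cell multiset.

    Every (modality, level) cell appears exactly ``repeats_per_cell`` times
    ("randomized order without replacement").  The shuffle is driven by a
    generator derived from ``config.rng_seed`` and the participant/run
    labels, so a fixed (seed, participant, run) always yields the same order.
    """
    cells = list(itertools.product(config.modalities, config.levels)) * config.repeats_per_cell
    rng = rng_stream(config.rng_seed, "schedule", participant_id, run_id)
    order = rng.permutation(len(cells))
    blocks = [
        BlockSpec(block_index=i, modality=cells[j][0], cued_level=cells[j][1])
        for i, j in enumerate(order)
    ]
    schedule = Schedule(participant_id=participant_id, run_id=run_id, blocks=blocks)
    return block_windows(config, schedule)


def block_windows(config: SessionConfig, schedule: Schedule) -> Schedule:
    """Fill in half-open TR windows, laid out back-to-back after stabilization."""
    t = config.stabilization_trs
    new_blocks = []
    for b in schedule.blocks:
        base = (t, t + config.baseline_trs)
        reg = (base[1], base[1] + config.regulation_trs)
        out = (reg[1], reg[1] + config.outcome_trs)
        new_blocks.append(
            replace(b, baseline_window=base, regulation_window=reg, outcome_window=out)
        )
        t = out[1]
    return Schedule(
        participant_id=schedule.participant_id,
        run_id=schedule.run_id,
        blocks=new_blocks,
        total_trs=t,
    )


def make_localizer_design(design: LocalizerDesign) -> np.ndarray:
    """Per-TR condition labels for the localizer, beginning and ending with rest."""
    labels: list[str] = []
    labels.extend(["rest"] * design.rest_trs)
    for _ in range(design.task_blocks):
        labels.extend(["task"] * design.task_trs)
        labels.extend(["rest"] * design.rest_trs)
    return np.array(labels)


def events_frame(config: SessionConfig, schedule: Schedule) -> pd.DataFrame:
    """BIDS-style events table: one row per phase of every block (onset/duration in s)."""
    rows = []
    for b in schedule.blocks:
        for phase, window in (
            ("baseline", b.baseline_window),
            ("regulation", b.regulation_window),
            ("outcome", b.outcome_window),
        ):
            if window is None:
                raise ConfigurationError("schedule windows not filled; call block_windows first")
            rows.append(
                {
                    "onset": window[0] * config.tr_seconds,
                    "duration": (window[1] - window[0]) * config.tr_seconds,
                    "trial_type": phase,
                    "modality": b.modality,
                    "cued_level": b.cued_level,
                    "block_index": b.block_index,
                }
            )
    return pd.DataFrame(rows)


def write_events(config: SessionConfig, schedule: Schedule, path) -> None:
    events_frame(config, schedule).to_csv(path, sep="\t", index=False)
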