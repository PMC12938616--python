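"""Per-TR feedback signal S(t), display mapping, and block-success scoring.

The feedback value for a TR is the ROI-mean percent signal change relative
to the mean of the immediately preceding baseline window, rescaled so that
the participant's localizer maximum sits at 100 on the display scale and
clipped to [0, 100].  Three target level ranges partition the upper display
scale: level 1 (weak) 10-40, level 2 (medium) 40-70, level 3 (strong) 70
and above (closed at 100 after clipping).

A block counts as successful when the feedback signal met or exceeded the
cued target level on at least half of the regulation TRs (>= 6 of 12 under
the defaults).  ``hit_rule="within_range"`` is available as an alternative
that additionally penalizes overshooting past the cued range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FeedbackComputationError,
    InputError,
)
from .paradigm import BlockSpec, Schedule, SessionConfig


@dataclass(frozen=True)
class CalibrationInfo:
    """The %dBOLD value mapped to 100 on the display scale."""

    localizer_max_percent: float

    def __post_init__(self) -> None:
        if not (self.localizer_max_percent > 0):
            raise ConfigurationError(
                f"localizer_max_percent must be > 0, got {self.localizer_max_percent}"
            )


@dataclass(frozen=True)
class TargetLevelSpec:
    """Half-open display range [range_lo, range_hi) for one cued level.

    The top level is closed at 100 (``upper_closed``) because the display
    scale is clipped there.
    """

    level: int
    range_lo: float
    range_hi: float
    upper_closed: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.range_lo < self.range_hi <= 100):
            raise ConfigurationError(
                f"invalid range [{self.range_lo}, {self.range_hi}] for level {self.level}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.range_lo + self.range_hi)

    def contains(self, s_value: float) -> bool:
        if self.upper_closed:
            return self.range_lo <= s_value <= self.range_hi
        return self.range_lo <= s_value < self.range_hi


def default_levels() -> dict[int, TargetLevelSpec]:
    """The a-priori level ranges: 10-40 (weak), 40-70 (medium), 70-100 (strong)."""
    return {
        1: TargetLevelSpec(1, 10.0, 40.0),
        2: TargetLevelSpec(2, 40.0, 70.0),
        3: TargetLevelSpec(3, 70.0, 100.0, upper_closed=True),
    }


@dataclass(frozen=True)
class ScoringConfig:
    hit_fraction: float = 0.5
    regulation_trs: int = 12
    hit_rule: str = "met_or_exceeded"
    grace_trs: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.hit_fraction <= 1):
            raise ConfigurationError(f"hit_fraction must be in (0, 1], got {self.hit_fraction}")
        if self.hit_rule not in ("met_or_exceeded", "within_range"):
            raise ConfigurationError(f"unknown hit_rule {self.hit_rule!r}")
        if self.grace_trs < 0 or self.grace_trs >= self.regulation_trs:
            raise ConfigurationError("grace_trs must be in [0, regulation_trs)")

    @property
    def success_threshold(self) -> int:
        """Minimal number of hit TRs for a successful block (6 under defaults)."""
        counted = self.regulation_trs - self.grace_trs
        return math.ceil(round(self.hit_fraction * counted, 9))


@dataclass
class FeedbackSample:
    """One regulation TR of the feedback stream."""

    tr_index: int
    raw_value: float
    psc: float
    s_value: float
    display_level: int
    display_fraction: float
    held: bool = False


@dataclass
class BlockOutcome:
    block_index: int
    modality: str
    cued_level: int
    n_hit_trs: int
    success: bool

    @property
    def outcome_display(self) -> str:
        return "green" if self.success else "red"


def baseline_mean(series: np.ndarray, block: BlockSpec) -> float:
    """Arithmetic mean of the series over the block's baseline window."""
    if block.baseline_window is None:
        raise InputError("block has no baseline window; run block_windows first")
    lo, hi = block.baseline_window
    series = np.asarray(series, dtype=float)
    if lo < 0 or hi > series.shape[0]:
        raise InputError(
            f"baseline window [{lo}, {hi}) outside series of length {series.shape[0]}"
        )
    return float(series[lo:hi].mean())


def percent_signal_change(raw: float, baseline: float) -> float:
    """%dBOLD of a raw ROI value relative to a (positive) baseline reference."""
    if not (baseline > 0):
        raise FeedbackComputationError(f"non-positive baseline {baseline}")
    return 100.0 * (raw - baseline) / baseline


def normalize(psc: float, cal: CalibrationInfo) -> float:
    """Rescale %dBOLD to the display scale and clip to [0, 100]."""
    s = 100.0 * psc / cal.localizer_max_percent
    return float(min(100.0, max(0.0, s)))


def level_for(s_value: float, levels: dict[int, TargetLevelSpec] | None = None) -> int:
    """Categorical display level for an S(t) value; 0 is the neutral face (< 10)."""
    levels = levels or default_levels()
    for lvl in sorted(levels, reverse=True):
        if s_value >= levels[lvl].range_lo:
            return lvl
    return 0


@dataclass(frozen=True)
class DisplayState:
    """What the participant sees this TR: a bar fraction, a face level, or nothing."""

    modality: str
    fraction: float | None = None
    level: int | None = None


def map_display(
    s_value: float, modality: str, levels: dict[int, TargetLevelSpec] | None = None
) -> DisplayState:
    if not (0 <= s_value <= 100):
        raise InputError(f"s_value {s_value} outside [0, 100]")
    if modality == "cFB":
        return DisplayState("cFB", fraction=s_value / 100.0)
    if modality == "aFB":
        return DisplayState("aFB", level=level_for(s_value, levels))
    if modality == "noFB":
        return DisplayState("noFB")
    raise InputError(f"unknown modality {modality!r}")


def is_hit(
    s_value: float,
    cued: TargetLevelSpec,
    hit_rule: str = "met_or_exceeded",
) -> bool:
    if hit_rule == "met_or_exceeded":
        return s_value >= cued.range_lo
    return cued.contains(s_value)


def classify_block(
    samples: Sequence[FeedbackSample] | Sequence[float],
    cued_level: int,
    scoring: ScoringConfig | None = None,
    levels: dict[int, TargetLevelSpec] | None = None,
    block_index: int = 0,
    modality: str = "cFB",
) -> BlockOutcome:
    """Classify one block from its regulation-TR feedback values.

    ``samples`` may be FeedbackSample objects or bare S(t) values.  A TR is
    a hit under the default rule iff S(t) reached the cued level's lower
    boundary; the block succeeds iff the hit count reaches
    ``scoring.success_threshold``.
    """
    scoring = scoring or ScoringConfig()
    levels = levels or default_levels()
    if cued_level not in levels:
        raise InputError(f"unknown cued level {cued_level}")
    s_values = [s.s_value if isinstance(s, FeedbackSample) else float(s) for s in samples]
    if len(s_values) != scoring.regulation_trs:
        raise InputError(
            f"expected {scoring.regulation_trs} regulation samples, got {len(s_values)}"
        )
    counted = s_values[scoring.grace_trs :]
    cued = levels[cued_level]
    n_hit = sum(1 for s in counted if is_hit(s, cued, scoring.hit_rule))
    return BlockOutcome(
        block_index=block_index,
        modality=modality,
        cued_level=cued_level,
        n_hit_trs=n_hit,
        success=n_hit >= scoring.success_threshold,
    )


def run_closed_loop(
    model,
    schedule: Schedule,
    cal: CalibrationInfo,
    config: SessionConfig,
    scoring: ScoringConfig | None = None,
    levels: dict[int, TargetLevelSpec] | None = None,
    rng: np.random.Generator | None = None,
    controller=None,
):
    """Simulate one run TR by TR, closing the loop between display and effort.

    Each TR the participant model advances its effort (reacting to the
    previous TR's display), the hemodynamic forward model produces the next
    raw ROI value, and the feedback chain (baseline reference -> %dBOLD ->
    S(t) -> display) yields the sample the participant sees next TR.  Block
    outcomes are appended at each outcome phase and drive the model's
    learning update.

    Returns ``(samples_df, outcomes, controller)`` where ``samples_df`` has
    one row per regulation TR.
    """
    # imported here to keep the scoring layer importable without the simulator
    from .synthetic import BoldSim, EffortController, ParticipantModel  # noqa: F401

    scoring = scoring or ScoringConfig(regulation_trs=config.regulation_trs)
    levels = levels or default_levels()
    if rng is None:
        rng = np.random.default_rng(0)
    if controller is None:
        controller = EffortController(model, cal, levels, rng=rng)

    n = schedule.total_trs
    if n is None:
        raise InputError("schedule has no windows; run block_windows first")
    sim = BoldSim(model, n, rng=rng, tr_seconds=config.tr_seconds)

    raw = np.empty(n)
    sample_rows: list[dict] = []
    outcomes: list[BlockOutcome] = []

    # map each TR to its block/phase for the sequential sweep
    phase_of = np.full(n, "stab", dtype=object)
    block_of = np.full(n, -1, dtype=int)
    for b in schedule.blocks:
        for phase, (lo, hi) in (
            ("baseline", b.baseline_window),
            ("regulation", b.regulation_window),
            ("outcome", b.outcome_window),
        ):
            phase_of[lo:hi] = phase
            block_of[lo:hi] = b.block_index

    block_samples: list[FeedbackSample] = []
    block_efforts: list[float] = []
    last_valid: FeedbackSample | None = None
    current_block: BlockSpec | None = None

    for t in range(n):
        phase = phase_of[t]
        if phase == "regulation":
            b = schedule.blocks[block_of[t]]
            if current_block is not b:
                current_block = b
                block_samples = []
                block_efforts = []
                controller.start_block(b)
                base_ref = baseline_mean(raw, b)
            effort = controller.effort
            raw[t] = sim.step(effort)
            block_efforts.append(effort)
            try:
                psc = percent_signal_change(raw[t], base_ref)
                s = normalize(psc, cal)
                sample = FeedbackSample(
                    tr_index=t,
                    raw_value=float(raw[t]),
                    psc=psc,
                    s_value=s,
                    display_level=level_for(s, levels),
                    display_fraction=s / 100.0,
                )
                last_valid = sample
            except FeedbackComputationError:
                # display holds the last valid state; held TRs still count
                held_s = last_valid.s_value if last_valid is not None else 0.0
                sample = FeedbackSample(
                    tr_index=t,
                    raw_value=float(raw[t]),
                    psc=float("nan"),
                    s_value=held_s,
                    display_level=level_for(held_s, levels),
                    display_fraction=held_s / 100.0,
                    held=True,
                )
            block_samples.append(sample)
            display = map_display(sample.s_value, b.modality, levels)
            controller.observe(display, cued=levels[b.cued_level])
            sample_rows.append(
                {
                    "tr_index": t,
                    "block_index": b.block_index,
                    "modality": b.modality,
                    "cued_level": b.cued_level,
                    "raw_value": sample.raw_value,
                    "psc": sample.psc,
                    "s_value": sample.s_value,
                    "display_level": sample.display_level if b.modality == "aFB" else np.nan,
                    "display_fraction": sample.display_fraction if b.modality == "cFB" else np.nan,
                    "held": sample.held,
                }
            )
        else:
            raw[t] = sim.step(0.0)
            if phase == "outcome" and block_of[t] >= 0:
                b = schedule.blocks[block_of[t]]
                if current_block is b:  # first outcome TR of the block
                    outcome = classify_block(
                        block_samples,
                        b.cued_level,
                        scoring,
                        levels,
                        block_index=b.block_index,
                        modality=b.modality,
                    )
                    outcomes.append(outcome)
                    # consolidate toward the corrected late-block effort
                    controller.end_block(
                        b,
                        success=outcome.success,
                        realized_effort=float(np.mean(block_efforts[-4:])),
                    )
                    current_block = None

    samples_df = pd.DataFrame(sample_rows)
    return samples_df, outcomes, controller


def outcomes_frame(
    outcomes: Iterable[BlockOutcome],
    schedule: Schedule | None = None,
) -> pd.DataFrame:
    rows = []
    for o in outcomes:
        row = {
            "block_index": o.block_index,
            "modality": o.modality,
            "cued_level": o.cued_level,
            "n_hit_trs": o.n_hit_trs,
            "success": o.success,
        }
        if schedule is not None:
            row["participant_id"] = schedule.participant_id
            row["run_id"] = schedule.run_id
        rows.append(row)
    return pd.DataFrame(rows)
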