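"""Synthetic participants, BOLD traces, localizer grids and latency logs.

This module is the study emulator: it generates everything the analysis
stack consumes, with the statistical structure the method assumes —
block-design ROI BOLD produced by convolving a behavioural effort signal
with a canonical double-gamma HRF, AR(1) innovations plus a slow linear
drift, per-participant activation gains in the %dBOLD range reported for
sensorimotor tapping (~1.5-4.5%), and right-skewed per-volume latency
distributions with rare heavy-tail outliers.

The behavioural model is deliberately simple.  A participant holds an
internal effort set-point per cued level (initialized so that the level's
display midpoint is hit given the participant's gain and calibration),
perturbed block-to-block by control noise.  During regulation the effort is
corrected each TR against the perceived display error — continuously for
the thermometer (cFB), coarsely for the categorical face (aFB), not at all
without feedback (noFB).  Learning is precision learning: after a
successful block the modality's control noise shrinks multiplicatively and
the set-point relaxes toward the realized effort, so modalities with a
positive learning rate show rising success across a session while the
others stay flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .errors import ConfigurationError, InputError
from .feedback import CalibrationInfo, DisplayState, TargetLevelSpec, default_levels
from .paradigm import (
    MODALITIES,
    BlockSpec,
    LocalizerDesign,
    make_localizer_design,
    rng_stream,
)


def double_gamma_hrf(
    tr_seconds: float,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    duration_s: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR, normalized to unit area.

    With a unit-area kernel the convolution of a sustained unit input
    converges to exactly 1, so the plateau of a block response equals the
    driving amplitude.
    """
    t = np.arange(0.0, duration_s + tr_seconds, tr_seconds)
    h = sp_stats.gamma.pdf(t, peak_s) - undershoot_ratio * sp_stats.gamma.pdf(t, undershoot_s)
    total = h.sum()
    if total <= 0:
        raise ConfigurationError("degenerate HRF parameters")
    return h / total


@dataclass(frozen=True)
class ParticipantModel:
    """Generative parameters of one synthetic participant."""

    participant_id: str = "S00"
    gain: float = 3.0  # %dBOLD at sustained unit effort
    effort_noise_sd: float = 0.12  # block-to-block control noise (effort units)
    init_bias_mean: float = -0.25  # shared display-to-effort mapping error (display fraction)
    init_bias_sd: float = 0.14
    cell_bias_sd: float = 0.08  # fixed per-(modality, level) set-point quirk
    tracking_rate_cFB: float = 0.045  # per-TR error-correction gains
    tracking_rate_aFB: float = 0.03
    tracking_rate_noFB: float = 0.0
    learning_rate_cFB: float = 0.17  # noise-shrink factor applied after successes
    learning_rate_aFB: float = 0.0
    learning_rate_noFB: float = 0.0
    ar_phi: float = 0.3  # AR(1) coefficient of the noise process
    noise_sd: float = 0.15  # innovation SD in %dBOLD
    drift_slope: float = 0.0  # %dBOLD per TR
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    field_strength: str = "3T"

    def __post_init__(self) -> None:
        if not (self.gain > 0):
            raise ConfigurationError("gain must be > 0")
        for name in (
            "tracking_rate_cFB",
            "tracking_rate_aFB",
            "tracking_rate_noFB",
            "learning_rate_cFB",
            "learning_rate_aFB",
            "learning_rate_noFB",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not (abs(self.ar_phi) < 1):
            raise ConfigurationError("|ar_phi| must be < 1")
        if self.noise_sd < 0 or self.effort_noise_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        if self.field_strength not in ("3T", "7T"):
            raise ConfigurationError("field_strength must be '3T' or '7T'")

    def tracking_rate(self, modality: str) -> float:
        return getattr(self, f"tracking_rate_{modality}")

    def learning_rate(self, modality: str) -> float:
        return getattr(self, f"learning_rate_{modality}")


# Field assignment of the emulated cohort: participants 1, 2 and 4 at 7T.
DEFAULT_FIELD_ASSIGNMENT: tuple[str, ...] = (
    "7T", "7T", "3T", "7T", "3T", "3T", "3T", "3T", "3T",
)

DEFAULT_MODEL_RANGES: dict[str, tuple[float, float]] = {
    "gain": (1.5, 4.5),
    "effort_noise_sd": (0.08, 0.14),
    "init_bias_mean": (-0.30, -0.20),
    "init_bias_sd": (0.10, 0.18),
    "cell_bias_sd": (0.05, 0.10),
    "tracking_rate_cFB": (0.03, 0.06),
    "tracking_rate_aFB": (0.02, 0.05),
    "tracking_rate_noFB": (0.0, 0.0),
    "learning_rate_cFB": (0.12, 0.22),
    "learning_rate_aFB": (0.0, 0.0),
    "learning_rate_noFB": (0.0, 0.0),
    "ar_phi": (0.2, 0.4),
    "noise_sd": (0.1, 0.2),
    "drift_slope": (-0.003, 0.003),
}


@dataclass(frozen=True)
class CohortSpec:
    n_participants: int = 9
    field_assignment: tuple[str, ...] = DEFAULT_FIELD_ASSIGNMENT
    model_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MODEL_RANGES)
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.field_assignment) != self.n_participants:
            raise ConfigurationError(
                "field_assignment length must equal n_participants"
            )
        for name, (lo, hi) in self.model_ranges.items():
            if hi < lo:
                raise ConfigurationError(f"empty sampling range for {name}: ({lo}, {hi})")


def sample_cohort(spec: CohortSpec) -> list[ParticipantModel]:
    """Draw ``n_participants`` models uniformly from the configured ranges."""
    models = []
    for i in range(spec.n_participants):
        pid = f"S{i + 1:02d}"
        rng = rng_stream(spec.master_seed, "cohort", pid)
        params = {
            name: float(rng.uniform(lo, hi)) for name, (lo, hi) in spec.model_ranges.items()
        }
        models.append(
            ParticipantModel(
                participant_id=pid,
                field_strength=spec.field_assignment[i],
                **params,
            )
        )
    return models


class EffortController:
    """Stateful behavioural controller of one participant across blocks/runs.

    Holds per-(modality, level) effort set-points and per-modality control
    noise, applies the per-TR tracking correction against the perceived
    display error, and performs the end-of-block learning update on
    successful blocks only.
    """

    def __init__(
        self,
        model: ParticipantModel,
        cal: CalibrationInfo,
        levels: dict[int, TargetLevelSpec] | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.model = model
        self.cal = cal
        self.levels = levels or default_levels()
        self.rng = rng if rng is not None else np.random.default_rng(0)
        # effort units per unit of display error (s/100); psc = gain * effort,
        # s = 100 * psc / cal  =>  ds/deffort = 100 * gain / cal
        self._err_scale = cal.localizer_max_percent / model.gain
        # The internal set-point for a cued level is the level's display
        # midpoint plus a shared display-to-effort mapping error per modality
        # (the learnable miscalibration) plus a small fixed per-cell quirk.
        self.map_bias: dict[str, float] = {
            m: self.rng.normal(model.init_bias_mean, model.init_bias_sd)
            for m in MODALITIES
        }
        self.cell_quirk: dict[tuple[str, int], float] = {
            (m, lvl): self.rng.normal(0.0, model.cell_bias_sd)
            for m in MODALITIES
            for lvl in self.levels
        }
        self.noise_sd: dict[str, float] = {m: model.effort_noise_sd for m in MODALITIES}
        self.effort: float = 0.0
        self._modality: str | None = None
        self._cued: int | None = None

    def target_fraction(self, modality: str, level: int) -> float:
        """Current internal aim for a cell, as a display fraction."""
        mid = self.levels[level].midpoint / 100.0
        return max(0.0, mid + self.map_bias[modality] + self.cell_quirk[(modality, level)])

    def setpoint(self, modality: str, level: int) -> float:
        """Current set-point in effort units."""
        return self.target_fraction(modality, level) * self._err_scale

    def start_block(self, block: BlockSpec) -> None:
        self._modality = block.modality
        self._cued = block.cued_level
        offset = self.rng.normal(0.0, self.noise_sd[block.modality])
        self.effort = max(0.0, self.setpoint(block.modality, block.cued_level) + offset)

    def observe(self, display: DisplayState, cued: TargetLevelSpec) -> None:
        """React to this TR's display; the correction applies from the next TR."""
        m = self._modality
        if m is None:
            raise InputError("observe() before start_block()")
        if m == "cFB" and display.fraction is not None:
            error = display.fraction * 100.0 / 100.0 - cued.midpoint / 100.0
        elif m == "aFB" and display.level is not None:
            error = (display.level - cued.level) / float(len(self.levels))
        else:  # noFB: nothing to react to during the block
            error = 0.0
        rate = self.model.tracking_rate(m)
        self.effort = max(0.0, self.effort - rate * error * self._err_scale)

    def end_block(self, block: BlockSpec, success: bool, realized_effort: float) -> None:
        """Outcome-driven update: only successful blocks teach.

        ``realized_effort`` should reflect the corrected late-block effort —
        the participant's best current estimate of what the cued level
        requires.  The shared mapping error relaxes toward the miscalibration
        that the successful block exposed, so one success recalibrates every
        level of that modality; the control noise shrinks multiplicatively
        (precision learning).
        """
        m = block.modality
        lr = self.model.learning_rate(m)
        if success and lr > 0:
            self.noise_sd[m] *= 1.0 - lr
            mid = self.levels[block.cued_level].midpoint / 100.0
            realized_f = realized_effort / self._err_scale
            exposed_bias = realized_f - mid - self.cell_quirk[(m, block.cued_level)]
            self.map_bias[m] = (1.0 - lr) * self.map_bias[m] + lr * exposed_bias
        self._modality = None
        self._cued = None


def effort_trace(
    model: ParticipantModel,
    block: BlockSpec,
    feedback_stream: Sequence | None,
    n_trs: int | None = None,
    cal: CalibrationInfo | None = None,
    levels: dict[int, TargetLevelSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Open-loop effort trace for one block given a precomputed feedback stream.

    ``feedback_stream`` carries per-TR S(t) values for cFB, per-TR displayed
    levels for aFB, and ``None`` for noFB (then ``n_trs`` is required).
    """
    levels = levels or default_levels()
    cal = cal or CalibrationInfo(model.gain)
    controller = EffortController(model, cal, levels, rng=rng)
    controller.start_block(block)
    cued = levels[block.cued_level]
    if feedback_stream is None:
        if n_trs is None:
            raise InputError("n_trs required when no feedback stream is given")
        items: list = [None] * n_trs
    else:
        items = list(feedback_stream)
    efforts = np.empty(len(items))
    for i, item in enumerate(items):
        efforts[i] = controller.effort
        if block.modality == "cFB":
            display = DisplayState("cFB", fraction=float(item) / 100.0)
        elif block.modality == "aFB":
            display = DisplayState("aFB", level=int(item))
        else:
            display = DisplayState("noFB")
        controller.observe(display, cued)
    return efforts


def simulate_bold(
    effort: np.ndarray,
    model: ParticipantModel,
    rng: np.random.Generator | int | None = None,
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Forward model: %dBOLD about a zero baseline for a full effort trace.

    output = (gain * effort) (x) HRF + linear drift + AR(1) noise.
    """
    effort = np.asarray(effort, dtype=float)
    n = effort.shape[0]
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    hrf = double_gamma_hrf(tr_seconds, model.hrf_peak_s, model.hrf_undershoot_s)
    task = np.convolve(model.gain * effort, hrf)[:n]
    drift = model.drift_slope * np.arange(n)
    if model.noise_sd > 0:
        eps = rng.normal(0.0, model.noise_sd, n)
        noise = sp_signal.lfilter([1.0], [1.0, -model.ar_phi], eps)
    else:
        noise = np.zeros(n)
    return task + drift + noise


class BoldSim:
    """Incremental TR-by-TR version of :func:`simulate_bold` on a raw scale.

    Returns raw ROI values on a baseline of 100 so the scoring chain
    (baseline mean -> %dBOLD) can be exercised exactly as online.
    """

    def __init__(
        self,
        model: ParticipantModel,
        n_trs: int,
        rng: np.random.Generator,
        tr_seconds: float = 2.0,
        baseline_raw: float = 100.0,
    ) -> None:
        self.model = model
        self.baseline_raw = baseline_raw
        self._hrf_rev = double_gamma_hrf(
            tr_seconds, model.hrf_peak_s, model.hrf_undershoot_s
        )[::-1].copy()
        self._L = self._hrf_rev.shape[0]
        self._efforts = np.zeros(n_trs + self._L)  # leading zero-padding
        self._eps = (
            rng.normal(0.0, model.noise_sd, n_trs)
            if model.noise_sd > 0
            else np.zeros(n_trs)
        )
        self._ar = 0.0
        self._t = 0

    def step(self, effort: float) -> float:
        t = self._t
        self._efforts[t + self._L - 1] = effort
        conv = float(np.dot(self._hrf_rev, self._efforts[t : t + self._L]))
        self._ar = self.model.ar_phi * self._ar + self._eps[t]
        pct = self.model.gain * conv + self.model.drift_slope * t + self._ar
        self._t = t + 1
        return self.baseline_raw * (1.0 + pct / 100.0)


def simulate_localizer_grid(
    model: ParticipantModel,
    design: LocalizerDesign,
    grid_shape: tuple[int, int, int],
    active_voxels: Iterable[tuple[int, int, int]],
    rng: np.random.Generator | int | None = None,
    baseline_raw: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Small 4D voxel-grid localizer time series plus the ground-truth mask.

    Active voxels carry the HRF-convolved task signal scaled by the
    participant's gain; every voxel carries independent AR(1) noise.
    Returns ``(data, mask)`` with ``data`` of shape ``grid_shape + (T,)``.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    mask = np.zeros(grid_shape, dtype=bool)
    for coord in active_voxels:
        if any(c < 0 or c >= s for c, s in zip(coord, grid_shape)):
            raise InputError(f"active voxel {coord} outside grid {grid_shape}")
        mask[tuple(coord)] = True
    labels = make_localizer_design(design)
    boxcar = (labels == "task").astype(float)
    hrf = double_gamma_hrf(design.tr_seconds, model.hrf_peak_s, model.hrf_undershoot_s)
    task_pct = model.gain * np.convolve(boxcar, hrf)[: boxcar.shape[0]]
    n_t = boxcar.shape[0]
    n_vox = int(np.prod(grid_shape))
    if model.noise_sd > 0:
        eps = rng.normal(0.0, model.noise_sd, (n_vox, n_t))
        noise = sp_signal.lfilter([1.0], [1.0, -model.ar_phi], eps, axis=1)
    else:
        noise = np.zeros((n_vox, n_t))
    pct = noise.reshape(grid_shape + (n_t,))
    pct[mask] += task_pct
    data = baseline_raw * (1.0 + pct / 100.0)
    return data, mask


@dataclass(frozen=True)
class LatencyModel:
    """Generator of per-volume transfer and processing latencies.

    Transfer/reconstruction latency is lognormal (right-skewed, median
    ``exp(transfer_log_mu)``); with probability ``outlier_prob`` a volume is
    replaced by a heavy-tail event well beyond the TR.  Processing time is a
    normal truncated at zero.
    """

    transfer_log_mu: float = float(np.log(454.0))
    transfer_log_sigma: float = 0.35
    processing_mean_ms: float = 300.0
    processing_sd_ms: float = 73.0
    outlier_prob: float = 0.0
    outlier_threshold_ms: float = 2000.0
    outlier_scale_ms: float = 3000.0

    def __post_init__(self) -> None:
        if not (0 <= self.outlier_prob <= 1):
            raise ConfigurationError("outlier_prob must lie in [0, 1]")
        if self.transfer_log_sigma < 0 or self.processing_sd_ms < 0:
            raise ConfigurationError("scale parameters must be non-negative")
        if self.outlier_scale_ms <= 0 or self.outlier_threshold_ms <= 0:
            raise ConfigurationError("outlier scales must be positive")


def simulate_latency_log(
    model: LatencyModel,
    n_volumes: int,
    seed: int | np.random.Generator,
    participant_id: str = "S00",
    field_strength: str = "3T",
    block_context: str = "",
) -> pd.DataFrame:
    """Per-volume latency log as a tidy table."""
    if n_volumes <= 0:
        raise InputError("n_volumes must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    transfer = rng.lognormal(model.transfer_log_mu, model.transfer_log_sigma, n_volumes)
    if model.outlier_prob > 0:
        tail = rng.random(n_volumes) < model.outlier_prob
        transfer[tail] = model.outlier_threshold_ms + rng.exponential(
            model.outlier_scale_ms, int(tail.sum())
        )
    if model.processing_sd_ms > 0:
        a = (0.0 - model.processing_mean_ms) / model.processing_sd_ms
        processing = sp_stats.truncnorm.rvs(
            a,
            np.inf,
            loc=model.processing_mean_ms,
            scale=model.processing_sd_ms,
            size=n_volumes,
            random_state=rng,
        )
    else:
        processing = np.full(n_volumes, model.processing_mean_ms)
    return pd.DataFrame(
        {
            "volume_index": np.arange(n_volumes),
            "transfer_ms": transfer,
            "processing_ms": processing,
            "participant_id": participant_id,
            "field_strength": field_strength,
            "block_context": block_context,
        }
    )
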