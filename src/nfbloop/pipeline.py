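"""End-to-end study driver: simulate cohort -> closed loop -> score -> analyze.

``simulate_session`` runs one participant's full session (all runs, shared
learning state); ``run_study`` drives the whole cohort and writes every
stage output (events, feedback streams, outcomes, summaries, learning
report, latency QC) plus a checksum manifest.  ``replicate_learning_deltas``
repeats the cohort simulation across seeds and collects the per-modality
run-to-run success deltas, the parameter-recovery readout used to validate
the generator's learning structure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import CalibrationError, ConfigurationError
from .feedback import (
    CalibrationInfo,
    ScoringConfig,
    default_levels,
    outcomes_frame,
    run_closed_loop,
)
from .inference import friedman, modality_learning_report
from .latency import flag_outliers, summarize
from .localizer import calibrate_max, fit_localizer, select_roi
from .metrics import aggregate, block_metrics_frame, learning_delta
from .paradigm import (
    LocalizerDesign,
    SessionConfig,
    events_frame,
    make_localizer_design,
    make_schedule,
    rng_stream,
)
from .synthetic import (
    CohortSpec,
    EffortController,
    LatencyModel,
    ParticipantModel,
    sample_cohort,
    simulate_bold,
    simulate_latency_log,
    simulate_localizer_grid,
)

logger = logging.getLogger("nfbloop")


@dataclass
class StudyConfig:
    """Top-level configuration of a simulated study."""

    session: SessionConfig = field(default_factory=SessionConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    localizer: LocalizerDesign = field(default_factory=LocalizerDesign)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    localizer_threshold_t: float = 5.0
    latency_outlier_prob_7t: float = 0.0036
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            session=SessionConfig(**raw.get("session", {})),
            cohort=CohortSpec(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw.get("cohort", {}).items()
            }),
            localizer=LocalizerDesign(**raw.get("localizer", {})),
            scoring=ScoringConfig(**raw.get("scoring", {})),
            localizer_threshold_t=raw.get("localizer_threshold_t", 5.0),
            latency_outlier_prob_7t=raw.get("latency_outlier_prob_7t", 0.0036),
            seed=raw.get("seed", 0),
        )


def calibrate_participant(
    model: ParticipantModel, design: LocalizerDesign, rng: np.random.Generator
) -> CalibrationInfo:
    """Localizer-style calibration from a simulated ROI trace.

    The participant performs the localizer at unit effort; the display
    maximum is the best task-block %dBOLD of that trace.  Falls back to the
    participant's gain if noise pushes the estimate non-positive.
    """
    labels = make_localizer_design(design)
    effort = (labels == "task").astype(float)
    trace = simulate_bold(effort, model, rng=rng, tr_seconds=design.tr_seconds)
    try:
        return calibrate_max(trace, design, percent_units=True)
    except CalibrationError:
        return CalibrationInfo(model.gain)


def simulate_session(
    model: ParticipantModel,
    config: SessionConfig,
    cal: CalibrationInfo | None = None,
    scoring: ScoringConfig | None = None,
    seed: int = 0,
    collect_samples: bool = False,
):
    """All runs of one participant with learning state carried across runs.

    Returns ``(outcomes_df, samples_df_or_None)``.
    """
    scoring = scoring or ScoringConfig(regulation_trs=config.regulation_trs)
    levels = default_levels()
    cal = cal or CalibrationInfo(model.gain)
    rng = rng_stream(seed, "session", model.participant_id)
    controller = EffortController(model, cal, levels, rng=rng)
    outcome_frames = []
    sample_frames = []
    for r in range(1, config.runs_per_session + 1):
        run_id = f"RUN{r}"
        schedule = make_schedule(config, model.participant_id, run_id)
        samples, outcomes, controller = run_closed_loop(
            model, schedule, cal, config, scoring, levels, rng=rng, controller=controller
        )
        of = outcomes_frame(outcomes, schedule)
        of["field_strength"] = model.field_strength
        outcome_frames.append(of)
        if collect_samples:
            samples["participant_id"] = model.participant_id
            samples["run_id"] = run_id
            sample_frames.append(samples)
    outcomes_df = pd.concat(outcome_frames, ignore_index=True)
    samples_df = pd.concat(sample_frames, ignore_index=True) if collect_samples else None
    return outcomes_df, samples_df


def simulate_cohort_outcomes(
    spec: CohortSpec | None = None,
    config: SessionConfig | None = None,
    scoring: ScoringConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Block outcomes for a full cohort (no file output; analysis-ready)."""
    spec = spec or CohortSpec(master_seed=seed)
    config = config or SessionConfig(rng_seed=seed)
    models = sample_cohort(spec)
    frames = [
        simulate_session(m, config, scoring=scoring, seed=seed)[0] for m in models
    ]
    return pd.concat(frames, ignore_index=True)


def replicate_learning_deltas(
    n_replicates: int,
    seed: int = 0,
    spec: CohortSpec | None = None,
    config: SessionConfig | None = None,
) -> pd.DataFrame:
    """Per-replicate mean RUN2-RUN1 success delta (pp) for each modality."""
    rows = []
    for rep in range(n_replicates):
        rep_seed = (seed + 7919 * (rep + 1)) % (2**31 - 1)
        rep_spec = spec or CohortSpec(master_seed=rep_seed)
        if spec is None:
            rep_spec = CohortSpec(master_seed=rep_seed)
        rep_config = config or SessionConfig(rng_seed=rep_seed)
        outcomes = simulate_cohort_outcomes(rep_spec, rep_config, seed=rep_seed)
        cells = aggregate(outcomes, by=("participant_id", "run_id", "modality"))
        deltas = learning_delta(cells)
        for modality, g in deltas.groupby("modality"):
            rows.append(
                {
                    "replicate": rep,
                    "modality": modality,
                    "mean_delta_pp": float(g["delta"].mean()),
                }
            )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(config: StudyConfig, out_dir, seed: int | None = None) -> dict:
    """Run the full pipeline and write all stage outputs under ``out_dir``.

    Stages: cohort sampling, per-participant localizer + ROI + calibration,
    closed-loop runs, per-TR streams and outcomes, cell summaries, learning
    report (with exact Wilcoxon p-values and the Friedman check), latency
    simulation and QC, and a manifest with SHA-256 checksums of every file.
    Deterministic for a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master_seed = config.seed if seed is None else seed
    session = config.session
    if session.rng_seed != master_seed:
        session = SessionConfig(**{**session.__dict__, "rng_seed": master_seed})
    spec = config.cohort
    if spec.master_seed != master_seed:
        spec = CohortSpec(
            n_participants=spec.n_participants,
            field_assignment=spec.field_assignment,
            model_ranges=spec.model_ranges,
            master_seed=master_seed,
        )
    logger.info("run_study: seed=%s participants=%s", master_seed, spec.n_participants)

    models = sample_cohort(spec)
    all_outcomes, all_samples, all_events, all_latency = [], [], [], []
    roi_records = []
    for model in models:
        pid = model.participant_id
        loc_rng = rng_stream(master_seed, "localizer", pid)
        # small planted-grid localizer: online GLM -> ROI -> calibration
        active = [(i, j, k) for i in (2, 3) for j in (2, 3) for k in (2, 3)]
        grid, _ = simulate_localizer_grid(
            model, config.localizer, (6, 6, 6), active, rng=loc_rng
        )
        stat_map = fit_localizer(grid, config.localizer)
        roi = select_roi(stat_map, config.localizer_threshold_t)
        trace = roi.mean_trace(grid)
        trace_pct = 100.0 * (trace / trace[: config.localizer.rest_trs].mean() - 1.0)
        try:
            cal = calibrate_max(trace_pct, config.localizer, percent_units=True)
        except CalibrationError:
            cal = CalibrationInfo(model.gain)
        roi_records.append(
            {
                "participant_id": pid,
                "field_strength": model.field_strength,
                "roi_size_voxels": roi.size_voxels,
                "roi_size_cm3": roi.size_cm3,
                "roi_peak_t": roi.peak_t,
                "localizer_max_percent": cal.localizer_max_percent,
            }
        )
        outcomes_df, samples_df = simulate_session(
            model, session, cal=cal, scoring=config.scoring,
            seed=master_seed, collect_samples=True,
        )
        all_outcomes.append(outcomes_df)
        all_samples.append(samples_df)
        for r in range(1, session.runs_per_session + 1):
            sched = make_schedule(session, pid, f"RUN{r}")
            ev = events_frame(session, sched)
            ev.insert(0, "participant_id", pid)
            ev.insert(1, "run_id", f"RUN{r}")
            all_events.append(ev)
        n_volumes = (
            session.runs_per_session * session.total_trs + config.localizer.total_trs
        )
        lat_model = LatencyModel(
            outlier_prob=(
                config.latency_outlier_prob_7t if model.field_strength == "7T" else 0.0
            )
        )
        all_latency.append(
            simulate_latency_log(
                lat_model,
                n_volumes,
                seed=rng_stream(master_seed, "latency", pid),
                participant_id=pid,
                field_strength=model.field_strength,
            )
        )

    outcomes = pd.concat(all_outcomes, ignore_index=True)
    samples = pd.concat(all_samples, ignore_index=True)
    events = pd.concat(all_events, ignore_index=True)
    latency_log = pd.concat(all_latency, ignore_index=True)

    metrics_df = block_metrics_frame(samples, config.scoring)
    outcomes_full = outcomes.merge(
        metrics_df.drop(columns=["modality", "cued_level"]),
        on=["participant_id", "run_id", "block_index"],
        how="left",
    )
    cells = aggregate(outcomes_full, by=("participant_id", "run_id", "modality"))

    if session.runs_per_session == 2:
        report = modality_learning_report(cells)
    else:
        logger.warning("learning analysis unavailable with %s run(s)", session.runs_per_session)
        report = pd.DataFrame()
    # condition comparison across modalities (session-pooled success rates)
    pooled = aggregate(outcomes_full, by=("participant_id", "modality"))
    matrix = pooled.pivot(index="participant_id", columns="modality", values="success_rate")
    fried = friedman(matrix.to_numpy())

    flagged, tallies = flag_outliers(latency_log)
    latency_report = {
        "overall_transfer": summarize(latency_log, "all")["all"].as_dict(),
        "overall_processing": summarize(latency_log, "all", column="processing_ms")[
            "all"
        ].as_dict(),
        "by_field_strength": {
            k: v.as_dict() for k, v in summarize(latency_log, "field_strength").items()
        },
        "outlier_tallies": {
            k: v for k, v in tallies.items() if not isinstance(v, dict)
        }
        | {k: dict(v) for k, v in tallies.items() if isinstance(v, dict)},
    }

    paths = {}

    def _write(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False, float_format="%.6f")
        paths[name] = path

    _write("events.tsv", events)
    _write("samples.tsv", samples)
    _write("outcomes.tsv", outcomes_full)
    _write("cell_summaries.tsv", cells)
    _write("roi_summary.tsv", pd.DataFrame(roi_records))
    if not report.empty:
        _write("learning_report.tsv", report)
    _write("latency_log.tsv", flagged)

    analysis = {
        "overall_success_rate": float(100.0 * outcomes["success"].mean()),
        "n_blocks": int(len(outcomes)),
        "friedman": {"chi2": fried.chi2, "df": fried.df, "p": fried.p},
        "latency": latency_report,
        "hit_rule": config.scoring.hit_rule,
    }
    analysis_path = out_dir / "analysis.json"
    analysis_path.write_text(json.dumps(analysis, indent=2, sort_keys=True))
    paths["analysis.json"] = analysis_path

    manifest = {
        "package_version": __version__,
        "seed": master_seed,
        "hit_rule": config.scoring.hit_rule,
        "n_participants": spec.n_participants,
        "outputs": {name: _sha256(p) for name, p in sorted(paths.items())},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "manifest": manifest,
        "outcomes": outcomes_full,
        "cells": cells,
        "report": report,
        "analysis": analysis,
    }
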