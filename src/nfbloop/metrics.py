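"""Block- and participant-level performance measures.

Beyond the binary success criterion, two continuous, task-congruent
measures are computed per block from the regulation-TR feedback values:

* occupancy — the proportion of regulation TRs whose feedback value lay
  within the cued target range (0-1);
* distance-to-range — per TR, 0 inside the range and otherwise the absolute
  distance to the nearest range boundary, summarized per block by its
  median (precision) and standard deviation (stability).

These always use within-range semantics regardless of the success-
classification hit rule.  The top level's range is [70, 100] on the clipped
display scale, so its upper boundary never contributes distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .feedback import FeedbackSample, ScoringConfig, TargetLevelSpec, default_levels


@dataclass
class BlockMetrics:
    occupancy: float
    dist_median: float
    dist_sd: float
    distances: np.ndarray


def distance_to_range(
    samples: Sequence[FeedbackSample] | Sequence[float],
    cued: TargetLevelSpec,
) -> np.ndarray:
    """Per-TR absolute distance to the cued range (0 inside)."""
    s_values = np.asarray(
        [s.s_value if isinstance(s, FeedbackSample) else float(s) for s in samples]
    )
    if s_values.size == 0:
        raise InputError("no samples")
    below = np.maximum(cued.range_lo - s_values, 0.0)
    if cued.upper_closed:
        above = np.zeros_like(s_values)  # clipped scale: no distance above the top level
    else:
        above = np.maximum(s_values - cued.range_hi, 0.0)
    dist = np.where(s_values < cued.range_lo, below, above)
    # half-open upper boundary: a value exactly at range_hi is outside at distance 0
    return dist


def block_metrics(
    samples: Sequence[FeedbackSample] | Sequence[float],
    cued_level: int,
    scoring: ScoringConfig | None = None,
    levels: dict[int, TargetLevelSpec] | None = None,
) -> BlockMetrics:
    scoring = scoring or ScoringConfig()
    levels = levels or default_levels()
    if len(samples) != scoring.regulation_trs:
        raise InputError(
            f"expected {scoring.regulation_trs} regulation samples, got {len(samples)}"
        )
    cued = levels[cued_level]
    dist = distance_to_range(samples, cued)
    s_values = np.asarray(
        [s.s_value if isinstance(s, FeedbackSample) else float(s) for s in samples]
    )
    inside = np.array([cued.contains(float(s)) for s in s_values])
    occupancy = float(inside.mean())
    return BlockMetrics(
        occupancy=occupancy,
        dist_median=float(np.median(dist)),
        dist_sd=float(np.std(dist, ddof=1)) if dist.size > 1 else 0.0,
        distances=dist,
    )


def block_metrics_frame(samples_df: pd.DataFrame, scoring: ScoringConfig | None = None,
                        levels: dict[int, TargetLevelSpec] | None = None) -> pd.DataFrame:
    """Per-block metrics from a per-TR feedback stream table."""
    scoring = scoring or ScoringConfig()
    rows = []
    group_keys = [k for k in ("participant_id", "run_id") if k in samples_df.columns]
    for key, g in samples_df.groupby(group_keys + ["block_index"], sort=True):
        m = block_metrics(g["s_value"].to_numpy(), int(g["cued_level"].iloc[0]), scoring, levels)
        row = dict(zip(group_keys + ["block_index"], key if isinstance(key, tuple) else (key,)))
        row.update(
            modality=g["modality"].iloc[0],
            cued_level=int(g["cued_level"].iloc[0]),
            occupancy=m.occupancy,
            dist_median=m.dist_median,
            dist_sd=m.dist_sd,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate(
    outcomes: pd.DataFrame,
    by: Sequence[str] = ("participant_id", "run_id", "modality"),
) -> pd.DataFrame:
    """Cell summaries: block counts, success counts/rates and mean metrics.

    ``success_rate`` is kept at full precision (percent); render to one
    decimal only in reports.  The result is independent of input row order.
    """
    by = list(by)
    missing = [c for c in by + ["success"] if c not in outcomes.columns]
    if missing:
        raise InputError(f"outcomes table lacks columns {missing}")
    if outcomes.empty:
        warnings.warn("empty outcomes table; no groups to aggregate")
        return pd.DataFrame(columns=by + ["n_blocks", "n_success", "success_rate"])
    rows = []
    for key, g in outcomes.groupby(by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        n = len(g)
        k = int(g["success"].sum())
        row.update(n_blocks=n, n_success=k, success_rate=100.0 * k / n)
        for col in ("occupancy", "dist_median", "dist_sd"):
            if col in g.columns:
                row[f"mean_{col}"] = float(g[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def learning_delta(
    summaries: pd.DataFrame,
    value: str = "success_rate",
    run_col: str = "run_id",
) -> pd.DataFrame:
    """Per-participant second-minus-first-run differences, per modality.

    Returns one row per (participant, modality) with the paired difference
    in the units of ``value`` (percentage points for success rates).
    Participants missing either run are excluded with a warning.
    """
    runs = sorted(summaries[run_col].unique())
    if len(runs) != 2:
        raise InputError(f"need exactly two runs, found {runs}")
    first, second = runs
    wide = summaries.pivot_table(
        index=["participant_id", "modality"], columns=run_col, values=value, aggfunc="first"
    )
    incomplete = wide[wide.isna().any(axis=1)]
    if not incomplete.empty:
        dropped = sorted({p for p, _ in incomplete.index})
        warnings.warn(f"participants missing a run excluded: {dropped}")
        wide = wide.dropna()
    out = wide.reset_index()
    out["delta"] = out[second] - out[first]
    return out.rename(columns={first: "run1_value", second: "run2_value"})


def learning_delta_stats(deltas: pd.DataFrame) -> pd.DataFrame:
    """Group mean/SD of the paired differences per modality."""
    rows = []
    for modality, g in deltas.groupby("modality", sort=True):
        rows.append(
            {
                "modality": modality,
                "n": len(g),
                "mean_delta": float(g["delta"].mean()),
                "sd_delta": float(g["delta"].std(ddof=1)) if len(g) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
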