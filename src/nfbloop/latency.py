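"""Latency quality control for the real-time pipeline.

Per-volume logs carry two components: transfer/reconstruction latency (from
image acquisition to arrival of the reconstructed volume at the feedback
workstation) and workstation processing time (real-time preprocessing,
statistics, feedback computation and rendering).  Summaries can be grouped
by participant or scanner field strength; heavy-tail outliers (strictly
above 2000 ms, the TR-scale truncation point) and TR-exceedance are flagged
per record.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import InputError

REQUIRED_COLUMNS = ("transfer_ms", "processing_ms")


@dataclass
class LatencySummary:
    group: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    iqr: float
    min: float
    max: float
    ci99_lo: float
    ci99_hi: float
    n_over_threshold: int
    pct_over_threshold: float
    end_to_end_mean: float

    def as_dict(self) -> dict:
        return asdict(self)


def _summary(group: str, g: pd.DataFrame, threshold_ms: float, column: str) -> LatencySummary:
    x = g[column].to_numpy(dtype=float)
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    q1, med, q3 = (float(q) for q in np.percentile(x, [25, 50, 75]))
    z99 = float(sp_stats.norm.ppf(0.995))
    half = z99 * sd / np.sqrt(n) if n > 0 else 0.0
    n_over = int((x > threshold_ms).sum())
    return LatencySummary(
        group=group,
        n=n,
        mean=mean,
        sd=sd,
        median=med,
        q1=q1,
        q3=q3,
        iqr=q3 - q1,
        min=float(x.min()),
        max=float(x.max()),
        ci99_lo=mean - half,
        ci99_hi=mean + half,
        n_over_threshold=n_over,
        pct_over_threshold=100.0 * n_over / n,
        end_to_end_mean=float(g["transfer_ms"].mean() + g["processing_ms"].mean()),
    )


def summarize(
    records: pd.DataFrame,
    group_by: str = "all",
    threshold_ms: float = 2000.0,
    column: str = "transfer_ms",
) -> dict[str, LatencySummary]:
    """Grouped latency summaries of one component (default: transfer).

    ``group_by`` is ``"all"``, ``"participant"`` or ``"field_strength"``.
    ``end_to_end_mean`` is always the sum of the group's transfer and
    processing means.  No records are dropped.
    """
    for col in REQUIRED_COLUMNS:
        if col not in records.columns:
            raise InputError(f"latency log lacks column {col!r}")
    if records.empty:
        raise InputError("empty latency log")
    if (records[list(REQUIRED_COLUMNS)].to_numpy() < 0).any():
        raise InputError("negative latencies in log")
    if group_by == "all":
        return {"all": _summary("all", records, threshold_ms, column)}
    key = {"participant": "participant_id", "field_strength": "field_strength"}.get(group_by)
    if key is None or key not in records.columns:
        raise InputError(f"cannot group by {group_by!r}")
    return {
        str(name): _summary(str(name), g, threshold_ms, column)
        for name, g in records.groupby(key, sort=True)
    }


def flag_outliers(
    records: pd.DataFrame,
    tail_threshold_ms: float = 2000.0,
    tr_ms: float = 2000.0,
    column: str = "transfer_ms",
) -> tuple[pd.DataFrame, dict]:
    """Flag heavy-tail and TR-exceeding volumes (both strict inequalities).

    Returns the log with ``tail`` / ``tr_exceeded`` boolean columns plus a
    tally dict: total counts and counts by block context and field strength
    for the tail events.
    """
    if tail_threshold_ms <= 0 or tr_ms <= 0:
        raise InputError("thresholds must be positive")
    out = records.copy()
    x = out[column].to_numpy(dtype=float)
    out["tail"] = x > tail_threshold_ms
    out["tr_exceeded"] = x > tr_ms
    tails = out[out["tail"]]
    tallies = {
        "n_tail": int(out["tail"].sum()),
        "n_tr_exceeded": int(out["tr_exceeded"].sum()),
        "tail_by_field_strength": tails.groupby("field_strength").size().to_dict()
        if "field_strength" in out.columns
        else {},
        "tail_by_block_context": tails.groupby("block_context").size().to_dict()
        if "block_context" in out.columns
        else {},
        "tail_by_participant": tails.groupby("participant_id").size().to_dict()
        if "participant_id" in out.columns
        else {},
    }
    return out, tallies
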