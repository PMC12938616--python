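"""Nonparametric inference on aggregated performance.

Implements the paired two-sided Wilcoxon signed-rank test with an exact
null distribution (full enumeration over sign assignments, mid-ranks for
ties, zeros discarded), Cohen's dz for paired designs, and the Friedman
test with tie correction.  The exact Wilcoxon is the workhorse for the
small within-subject samples this design produces (n = 9 participants).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import DegenerateDataError, InputError
from .metrics import learning_delta

EXACT_CUTOFF = 20  # full enumeration up to here; normal approximation beyond


@dataclass
class PairedTestResult:
    n_input: int
    n_effective: int
    w_statistic: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx" | "degenerate"
    cohens_dz: float | None = None


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    n_subjects: int
    k_conditions: int
    tie_corrected: bool


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks of |d| (zeros removed) and the signs of the differences."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sp_stats.rankdata(np.abs(d))
    return ranks, np.sign(d)


def _exact_two_sided_p(ranks: np.ndarray, w_min: float) -> float:
    """P-value by enumerating the 2^n equiprobable sign assignments.

    Ranks are mid-ranks, i.e. multiples of 1/2; doubling maps the positive
    rank sum onto an integer lattice so the null distribution can be built
    by polynomial (subset-sum) convolution — equivalent to, but much
    cheaper than, materializing all 2^n patterns.
    """
    ranks2 = np.rint(2 * ranks).astype(int)
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    w2 = int(np.rint(2 * w_min))  # observed W on the doubled lattice
    cdf = counts[: w2 + 1].sum() / counts.sum()
    return float(min(1.0, 2.0 * cdf))


def wilcoxon_exact(diffs, zero_method: str = "wilcox", exact_cutoff: int = EXACT_CUTOFF) -> PairedTestResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are discarded (Wilcoxon's original procedure); ties
    among |d| receive mid-ranks.  W is the smaller of the positive and
    negative rank sums.  For ``n_effective <= exact_cutoff`` the two-sided
    p-value is exact: ``min(1, 2 * P(W <= w_obs))`` under the enumeration
    null; beyond that a normal approximation with tie and continuity
    corrections is used.

    All-zero differences are degenerate: no evidence, p = 1.
    """
    if zero_method != "wilcox":
        raise InputError("only zero_method='wilcox' (discard zeros) is implemented")
    d = np.asarray(diffs, dtype=float)
    n_input = d.size
    dz = _dz_or_none(d)
    nz = d[d != 0]
    if nz.size == 0:
        return PairedTestResult(n_input, 0, 0.0, 1.0, "degenerate", dz)
    ranks, signs = _signed_ranks(d)
    w_pos = float(ranks[signs > 0].sum())
    w_neg = float(ranks[signs < 0].sum())
    w = min(w_pos, w_neg)
    n_eff = nz.size
    if n_eff <= exact_cutoff:
        p = _exact_two_sided_p(ranks, w)
        method = "exact"
    else:
        mean = n_eff * (n_eff + 1) / 4.0
        # tie correction on the variance
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / 48.0
        var = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0 - tie_term
        z = (w - mean + 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sp_stats.norm.cdf(z)))
        method = "normal_approx"
    return PairedTestResult(n_input, n_eff, w, p, method, dz)


def _dz_or_none(diffs: np.ndarray) -> float | None:
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        return None
    sd = d.std(ddof=1)
    if sd == 0:
        return None
    return float(d.mean() / sd)


def cohens_dz(diffs) -> float:
    """Paired effect size: mean difference over the (n-1) SD of differences."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise DegenerateDataError("need at least 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance differences: dz undefined")
    return float(d.mean() / sd)


def friedman(matrix) -> FriedmanResult:
    """Friedman test on a subjects x conditions matrix, with tie correction.

    chi2 = (k - 1) * sum_j (R_j - n(k+1)/2)^2 / (A - C) where A is the sum
    of squared within-subject mid-ranks and C = n k (k+1)^2 / 4; without
    ties this reduces to the textbook 12/(nk(k+1)) sum R_j^2 - 3n(k+1).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise InputError("matrix must be 2-D (subjects x conditions)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InputError(f"need >= 2 subjects and >= 2 conditions, got {n} x {k}")
    ranks = np.apply_along_axis(sp_stats.rankdata, 1, x)
    col_sums = ranks.sum(axis=0)
    a = float((ranks**2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    tie_corrected = bool(not np.allclose(np.sort(ranks, axis=1), np.arange(1, k + 1)))
    if np.isclose(a, c):
        # every subject ranks all conditions equally: no discrimination at all
        return FriedmanResult(0.0, k - 1, 1.0, n, k, tie_corrected)
    chi2 = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum()) / (a - c)
    p = float(sp_stats.chi2.sf(chi2, k - 1))
    return FriedmanResult(chi2, k - 1, p, n, k, tie_corrected)


def modality_learning_report(
    summaries: pd.DataFrame,
    value: str = "success_rate",
) -> pd.DataFrame:
    """Per-modality learning table: run means, Δ (run2 − run1), dz and exact p.

    ``summaries`` is a cell-summary table with one row per participant x
    run x modality.  A pooled row aggregates each participant's rate across
    modalities (block-weighted) before differencing.
    """
    deltas = learning_delta(summaries, value=value)
    rows = []
    pooled = None
    if {"n_blocks", "n_success"}.issubset(summaries.columns):
        per_part = (
            summaries.groupby(["participant_id", "run_id"], sort=True)[["n_blocks", "n_success"]]
            .sum()
            .reset_index()
        )
        per_part[value] = 100.0 * per_part["n_success"] / per_part["n_blocks"]
        per_part["modality"] = "all"
        pooled = learning_delta(per_part, value=value)
    for modality, g in list(deltas.groupby("modality", sort=True)) + (
        [("all", pooled)] if pooled is not None else []
    ):
        d = g["delta"].to_numpy()
        res = wilcoxon_exact(d)
        rows.append(
            {
                "modality": modality,
                "n": len(g),
                "m_run1": float(g["run1_value"].mean()),
                "sd_run1": float(g["run1_value"].std(ddof=1)) if len(g) > 1 else 0.0,
                "m_run2": float(g["run2_value"].mean()),
                "sd_run2": float(g["run2_value"].std(ddof=1)) if len(g) > 1 else 0.0,
                "delta": float(d.mean()),
                "cohens_dz": res.cohens_dz if res.cohens_dz is not None else np.nan,
                "p_wilcoxon": res.p_two_sided,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)
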