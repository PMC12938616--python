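"""Streaming localizer GLM, per-voxel t-maps, ROI selection and calibration.

The online GLM accumulates the design/data cross-products volume by volume,
so after any number of updates the estimates are algebraically identical to
batch least squares on the volumes seen so far while each update costs
O(voxels).  The design is the standard task model: an HRF-convolved task
boxcar, an intercept, and a linear trend; the contrast of interest is the
task coefficient (tapping versus fixation).

ROI selection thresholds the t-map and returns the face-connected cluster
containing the global t maximum — the "most significant" cluster — with
size bookkeeping at the acquisition voxel volume of 2 x 2 x 3 mm^3
(0.012 cm^3 per voxel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, EmptyRoiError, EstimationError, InputError
from .feedback import CalibrationInfo
from .paradigm import LocalizerDesign, make_localizer_design
from .synthetic import double_gamma_hrf

VOXEL_CM3 = 0.012  # 2 x 2 x 3 mm^3 acquisition voxels

_VARIANCE_FLOOR = 1e-12  # keeps t finite on noise-free synthetic fixtures


def localizer_design_matrix(design: LocalizerDesign) -> np.ndarray:
    """Design matrix (T x 3): HRF-convolved task boxcar, intercept, linear trend."""
    labels = make_localizer_design(design)
    boxcar = (labels == "task").astype(float)
    hrf = double_gamma_hrf(design.tr_seconds)
    task = np.convolve(boxcar, hrf)[: boxcar.shape[0]]
    n = boxcar.shape[0]
    trend = np.linspace(-1.0, 1.0, n)
    return np.column_stack([task, np.ones(n), trend])


@dataclass
class StatMap:
    """Per-voxel t-statistics for one contrast."""

    t: np.ndarray  # grid-shaped
    df: int
    contrast: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.t.shape


@dataclass
class RoiMask:
    """A connected suprathreshold cluster."""

    voxels: np.ndarray  # (n, 3) integer coordinates
    peak_t: float
    peak_coord: tuple[int, int, int]
    grid_shape: tuple[int, int, int]

    @property
    def size_voxels(self) -> int:
        return int(self.voxels.shape[0])

    @property
    def size_cm3(self) -> float:
        return VOXEL_CM3 * self.size_voxels

    def as_bool(self) -> np.ndarray:
        mask = np.zeros(self.grid_shape, dtype=bool)
        mask[tuple(self.voxels.T)] = True
        return mask

    def mean_trace(self, data: np.ndarray) -> np.ndarray:
        """ROI-mean time series from a ``grid + (T,)`` array."""
        return data[self.as_bool()].mean(axis=0)


class GlmState:
    """Running cross-products of an incremental voxel-wise GLM.

    ``design`` is the full (planned) design matrix; rows are consumed in
    acquisition order as volumes arrive.
    """

    def __init__(self, design: np.ndarray, grid_shape: tuple[int, ...]) -> None:
        design = np.asarray(design, dtype=float)
        if design.ndim != 2:
            raise InputError("design must be a 2-D matrix")
        self.design = design
        self.grid_shape = tuple(grid_shape)
        self.n_voxels = int(np.prod(grid_shape))
        p = design.shape[1]
        self.xtx = np.zeros((p, p))
        self.xty = np.zeros((p, self.n_voxels))
        self.yty = np.zeros(self.n_voxels)
        self.n_volumes_seen = 0

    def update(self, volume: np.ndarray) -> "GlmState":
        volume = np.asarray(volume, dtype=float)
        if volume.shape != self.grid_shape and volume.shape != (self.n_voxels,):
            raise InputError(
                f"volume shape {volume.shape} does not match grid {self.grid_shape}"
            )
        if self.n_volumes_seen >= self.design.shape[0]:
            raise InputError("more volumes than design rows")
        y = volume.reshape(-1)
        x = self.design[self.n_volumes_seen]
        self.xtx += np.outer(x, x)
        self.xty += np.outer(x, y)
        self.yty += y * y
        self.n_volumes_seen += 1
        return self

    # ----- estimates -----

    def _solve(self) -> tuple[np.ndarray, np.ndarray, int]:
        if self.n_volumes_seen == 0:
            raise EstimationError("no volumes seen")
        rank = int(np.linalg.matrix_rank(self.xtx))
        df = self.n_volumes_seen - rank
        if rank < self.xtx.shape[0]:
            raise EstimationError("singular design over the volumes seen")
        beta = np.linalg.solve(self.xtx, self.xty)
        return beta, self.xtx, df

    def betas(self) -> np.ndarray:
        """Per-voxel coefficient estimates, shape (p, n_voxels)."""
        return self._solve()[0]

    def t_map(self, contrast: np.ndarray) -> StatMap:
        contrast = np.asarray(contrast, dtype=float)
        beta, xtx, df = self._solve()
        if df <= 0:
            raise EstimationError(
                f"not enough volumes ({self.n_volumes_seen}) for the design rank"
            )
        rss = self.yty - np.einsum("pv,pv->v", beta, self.xty)
        sigma2 = np.maximum(rss / df, _VARIANCE_FLOOR)
        cvc = float(contrast @ np.linalg.solve(xtx, contrast))
        t = (contrast @ beta) / np.sqrt(sigma2 * cvc)
        return StatMap(t=t.reshape(self.grid_shape), df=df, contrast=contrast)


def glm_update(state: GlmState, new_volume: np.ndarray) -> GlmState:
    return state.update(new_volume)


def t_map(state: GlmState, contrast: np.ndarray) -> StatMap:
    return state.t_map(contrast)


def fit_localizer(
    data: np.ndarray, design: LocalizerDesign, contrast=(1.0, 0.0, 0.0)
) -> StatMap:
    """Convenience: stream a full ``grid + (T,)`` array through the online GLM."""
    X = localizer_design_matrix(design)
    grid_shape = data.shape[:-1]
    state = GlmState(X, grid_shape)
    for t in range(data.shape[-1]):
        state.update(data[..., t])
    return state.t_map(np.asarray(contrast))


def select_roi(stat_map: StatMap, threshold_t: float, prior_mask: np.ndarray | None = None) -> RoiMask:
    """Threshold the t-map and return the cluster holding the global peak.

    Clusters are defined by face adjacency (6-connectivity).  Ties on the
    peak value are broken by larger cluster size, then by the
    lexicographically smallest peak coordinate.  ``prior_mask`` optionally
    restricts the search (the stand-in for an anatomical constraint).
    """
    if not (threshold_t > 0):
        raise InputError("threshold_t must be > 0")
    t = stat_map.t
    supra = t > threshold_t
    if prior_mask is not None:
        supra &= np.asarray(prior_mask, dtype=bool)
    if not supra.any():
        raise EmptyRoiError(f"no voxel exceeds t = {threshold_t}")
    structure = ndimage.generate_binary_structure(t.ndim, 1)  # faces only
    labels, n_clusters = ndimage.label(supra, structure=structure)
    best: tuple | None = None
    for label in range(1, n_clusters + 1):
        cluster = labels == label
        peak_val = t[cluster].max()
        coords = np.argwhere(cluster & (t == peak_val))
        peak_coord = tuple(int(c) for c in sorted(map(tuple, coords))[0])
        key = (-peak_val, -int(cluster.sum()), peak_coord)
        if best is None or key < best[0]:
            best = (key, cluster, peak_val, peak_coord)
    _, cluster, peak_val, peak_coord = best
    voxels = np.argwhere(cluster)
    return RoiMask(
        voxels=voxels,
        peak_t=float(peak_val),
        peak_coord=peak_coord,
        grid_shape=t.shape,
    )


def calibrate_max(
    series: np.ndarray,
    design: LocalizerDesign,
    percent_units: bool = True,
) -> CalibrationInfo:
    """Display-scale calibration from the ROI-mean localizer trace.

    The calibration point is the maximum block-averaged %dBOLD across task
    blocks, each referenced to the mean of its immediately preceding rest
    block (a block mean rather than a single-TR peak, to keep the 100%
    point off noise spikes).  ``percent_units=True`` treats the series as
    %dBOLD about zero (block difference); otherwise as raw intensities
    (ratio to the rest mean).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] != design.total_trs:
        raise InputError(
            f"series length {series.shape[0]} does not match design ({design.total_trs} TRs)"
        )
    block_psc = []
    t = design.rest_trs
    for _ in range(design.task_blocks):
        rest_mean = series[t - design.rest_trs : t].mean()
        task_mean = series[t : t + design.task_trs].mean()
        if percent_units:
            block_psc.append(task_mean - rest_mean)
        else:
            if rest_mean <= 0:
                raise CalibrationError("non-positive rest reference")
            block_psc.append(100.0 * (task_mean - rest_mean) / rest_mean)
        t += design.task_trs + design.rest_trs
    max_pct = float(max(block_psc))
    if max_pct <= 0:
        raise CalibrationError(f"non-positive localizer maximum ({max_pct:.3g}%)")
    return CalibrationInfo(localizer_max_percent=max_pct)
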