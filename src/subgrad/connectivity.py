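"""Functional-connectivity matrices and basic QC.

Subject-level FC is the Pearson correlation between every subcortical voxel
time series and every cortical ROI time series; matrices are Fisher
r-to-z transformed, averaged across subjects for group-level analyses, and
sparsified by retaining the top fraction of connections per voxel row.
SFNR (temporal mean over temporal standard deviation) and the T1w/T2w
ratio map round out the quality-control surface.

Numerical conventions used throughout (documented constants): sample
standard deviation (ddof=1), Fisher clipping of |r| at 1 - 1e-7, ceiling
retained counts with ties broken by lowest column index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

FISHER_CLIP = 1.0 - 1e-7


@dataclass
class FCMatrix:
    """Voxels x cortical-ROIs connectivity with its transform state."""

    values: np.ndarray
    transform: str = "r"                 # "r" | "fisher_z"
    sparsified: bool = False
    retained_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("FC values must be a voxels x ROIs matrix")
        if np.any(np.isnan(self.values)):
            raise ValueError("FC matrix contains NaN")
        if self.transform not in ("r", "fisher_z"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


def _standardize_rows(ts: np.ndarray, what: str) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    mean = ts.mean(axis=1, keepdims=True)
    sd = ts.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd[:, 0] == 0)
    if bad.size:
        raise ValueError(f"zero-variance {what} series at rows {bad.tolist()}")
    return (ts - mean) / sd


def compute_fc(voxel_ts: np.ndarray, roi_ts: np.ndarray) -> FCMatrix:
    """Pearson correlation of each voxel series with each ROI series.

    Runs may be concatenated in time by the caller before this call.
    """
    voxel_ts = np.asarray(voxel_ts, dtype=float)
    roi_ts = np.asarray(roi_ts, dtype=float)
    if voxel_ts.ndim != 2 or roi_ts.ndim != 2:
        raise ValueError("time series must be 2-D (rows x time)")
    if voxel_ts.shape[1] != roi_ts.shape[1]:
        raise ValueError("voxel and ROI series must share the time axis")
    if voxel_ts.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    vx = _standardize_rows(voxel_ts, "voxel")
    rx = _standardize_rows(roi_ts, "ROI")
    r = (vx @ rx.T) / (voxel_ts.shape[1] - 1)
    np.clip(r, -1.0, 1.0, out=r)
    return FCMatrix(values=r, transform="r")


def fisher_z(fc: FCMatrix, clip: float = FISHER_CLIP) -> FCMatrix:
    """Fisher r-to-z transform, atanh(r) with |r| clipped below 1."""
    if fc.transform != "r":
        raise ValueError("fisher_z expects an untransformed (r) matrix")
    z = np.arctanh(np.clip(fc.values, -clip, clip))
    return replace(fc, values=z, transform="fisher_z")


def threshold_top_fraction(
    fc: FCMatrix, fraction: float = 0.10, per_row: bool = True
) -> FCMatrix:
    """Retain the top ``fraction`` of connections.

    Row-wise (default): per row the k = ceil(fraction * n_rois) largest
    entries by signed value are kept, ties broken by lowest column index.
    ``per_row=False`` thresholds over the whole matrix instead (top
    ceil(fraction * n_entries) entries, ties by flat index).  Everything
    else becomes exactly 0, and re-applying with the same fraction is a
    no-op.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fc.sparsified and fc.retained_fraction == fraction:
        return replace(fc, values=fc.values.copy())
    out = np.zeros_like(fc.values)
    if per_row:
        k = math.ceil(fraction * fc.n_rois)
        # stable sort on the negated row: descending by value, ties by low index
        order = np.argsort(-fc.values, axis=1, kind="stable")
        keep = order[:, :k]
        rows = np.arange(fc.n_voxels)[:, None]
        out[rows, keep] = fc.values[rows, keep]
    else:
        flat = fc.values.ravel()
        k = math.ceil(fraction * flat.size)
        keep = np.argsort(-flat, kind="stable")[:k]
        out_flat = out.ravel()
        out_flat[keep] = flat[keep]
    return replace(fc, values=out, sparsified=True, retained_fraction=fraction)


def group_average_fc(fcs: list[FCMatrix]) -> FCMatrix:
    """Elementwise mean of unsparsified same-transform FC matrices."""
    if not fcs:
        raise ValueError("need at least one FC matrix")
    first = fcs[0]
    for fc in fcs:
        if fc.values.shape != first.values.shape:
            raise ValueError("FC matrices must share a shape to be averaged")
        if fc.transform != first.transform:
            raise ValueError("FC matrices must share a transform to be averaged")
        if fc.sparsified:
            raise ValueError("average unsparsified matrices, then re-threshold")
    mean = np.mean([fc.values for fc in fcs], axis=0)
    return FCMatrix(values=mean, transform=first.transform)


def sfnr(ts: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, float]:
    """Signal-to-fluctuation-noise ratio per voxel plus the mask mean.

    Temporal mean divided by temporal standard deviation; zero-variance
    voxels are returned NaN and excluded from the mask mean with a warning.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 2:
        raise ValueError("time series must be voxels x T with T >= 2")
    mean = ts.mean(axis=1)
    sd = ts.std(axis=1, ddof=ddof)
    vals = np.full(ts.shape[0], np.nan)
    ok = sd > 0
    vals[ok] = mean[ok] / sd[ok]
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} zero-variance voxel(s) excluded from SFNR mean",
            RuntimeWarning,
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("every voxel has zero temporal variance")
    return vals, float(vals[ok].mean())


def t1t2_ratio(
    t1w_map: np.ndarray, t2w_map: np.ndarray, zscore: bool = False
) -> np.ndarray:
    """Elementwise T1w/T2w ratio, optionally z-scored over in-mask voxels."""
    t1 = np.asarray(t1w_map, dtype=float)
    t2 = np.asarray(t2w_map, dtype=float)
    if t1.shape != t2.shape:
        raise ValueError("T1w and T2w maps must share a geometry")
    n_bad = int(np.sum(t2 <= 0))
    if n_bad:
        raise ValueError(f"{n_bad} voxel(s) with non-positive T2w inside the mask")
    ratio = t1 / t2
    if zscore:
        sd = ratio.std(ddof=1)
        if sd == 0:
            raise ValueError("cannot z-score a constant ratio map")
        ratio = (ratio - ratio.mean()) / sd
    return ratio
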