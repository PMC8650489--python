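"""ROI time-series handling: extraction, motion censoring, task selection.

The connectivity stage consumes one matrix per subject whose rows are
ROI-averaged signals over the volumes retained for analysis.  Volumes are
retained when (a) they fall inside a task block and (b) their differential
head movement does not exceed the censoring threshold (default 0.5 mm per
TR, strictly greater-than censored; a volume at exactly the threshold is
kept).  Censored volumes are dropped outright, never interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROITimeSeries",
    "CensorMask",
    "extract_roi_timeseries",
    "censor_motion",
    "select_task_volumes",
]


@dataclass
class ROITimeSeries:
    """ROI x volume signal matrix with provenance of the retained volumes.

    ``volume_index`` holds the original acquisition indices of the columns,
    so downstream code can always tell which volumes survived censoring and
    task selection.
    """

    values: np.ndarray
    roi_names: list[str]
    tr_s: float
    volume_index: np.ndarray = field(default=None)  # type: ignore[assignment]
    dropped_rois: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (ROI x volume)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite values")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("roi_names must be unique")
        if len(self.roi_names) != self.values.shape[0]:
            raise ValueError("roi_names length does not match row count")
        if self.volume_index is None:
            self.volume_index = np.arange(self.values.shape[1])
        self.volume_index = np.asarray(self.volume_index, dtype=np.int64)
        if self.volume_index.shape != (self.values.shape[1],):
            raise ValueError("volume_index length does not match column count")
        if self.volume_index.size > 1 and np.any(np.diff(self.volume_index) <= 0):
            raise ValueError("volume_index must be strictly increasing")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CensorMask:
    """Per-volume keep mask derived from a motion trace."""

    keep: np.ndarray
    threshold_mm: float

    @property
    def n_kept(self) -> int:
        return int(np.count_nonzero(self.keep))


def extract_roi_timeseries(volume4d: np.ndarray, labels: np.ndarray,
                           roi_names: list[str] | None = None,
                           tr_s: float = 2.5) -> ROITimeSeries:
    """Voxelwise-average a 4-D volume into per-ROI time series.

    Row r of the output is the arithmetic mean, per volume, over all voxels
    carrying the r-th nonzero label; label 0 is background.  ROIs are
    ordered by ascending label.  Labels present in ``roi_names`` but absent
    from the volume are excluded with a warning and recorded in
    ``dropped_rois``.
    """
    vol = np.asarray(volume4d, dtype=float)
    lab = np.asarray(labels)
    if vol.ndim != 4:
        raise ValueError(f"volume4d must be 4-D, got ndim={vol.ndim}")
    if lab.shape != vol.shape[:3]:
        raise ValueError(
            f"label volume shape {lab.shape} does not match spatial dims {vol.shape[:3]}")
    present = np.unique(lab)
    present = present[present > 0]
    if present.size == 0:
        raise ValueError("label volume contains no nonzero labels")

    if roi_names is not None:
        n_named = len(roi_names)
        expected = np.arange(1, n_named + 1)
        missing = np.setdiff1d(expected, present)
        dropped = [roi_names[i - 1] for i in missing]
        if dropped:
            warnings.warn(
                f"{len(dropped)} labeled ROI(s) own no voxels and were excluded: "
                + ", ".join(dropped), stacklevel=2)
        names = [roi_names[int(l) - 1] for l in present]
    else:
        dropped = []
        names = [f"roi_{int(l):04d}" for l in present]

    flat_lab = lab.ravel()
    n_vol = vol.shape[3]
    flat_vol = vol.reshape(-1, n_vol)
    max_lab = int(present.max())
    counts = np.bincount(flat_lab.ravel().astype(np.int64), minlength=max_lab + 1)
    sums = np.zeros((max_lab + 1, n_vol))
    np.add.at(sums, flat_lab.astype(np.int64), flat_vol)
    means = sums[present.astype(np.int64)] / counts[present.astype(np.int64), None]
    return ROITimeSeries(values=means, roi_names=names, tr_s=tr_s,
                         dropped_rois=dropped)


def censor_motion(motion: np.ndarray, threshold_mm: float = 0.5) -> CensorMask:
    """Keep mask over volumes: keep[t] iff differential movement <= threshold.

    Movement strictly above the threshold is censored; a volume at exactly
    the threshold is kept.
    """
    m = np.asarray(motion, dtype=float).ravel()
    if not np.all(np.isfinite(m)):
        raise ValueError("motion trace contains non-finite values")
    if np.any(m < 0):
        raise ValueError("motion trace must be non-negative (mm per TR)")
    return CensorMask(keep=m <= threshold_mm, threshold_mm=float(threshold_mm))


def select_task_volumes(ts: ROITimeSeries, design, censor: CensorMask | None = None) -> ROITimeSeries:
    """Restrict a time series to uncensored task-block volumes.

    The retained set is the intersection ``task_mask AND keep``; the two
    masks commute, so censoring before or after task selection is
    equivalent.  Retaining zero volumes is a hard error.
    """
    task_mask = np.asarray(design.task_mask, dtype=bool)
    if task_mask.size != ts.n_volumes:
        raise ValueError(
            f"task mask length {task_mask.size} != {ts.n_volumes} volumes")
    if censor is None:
        keep = task_mask
    else:
        ck = np.asarray(censor.keep, dtype=bool)
        if ck.size != ts.n_volumes:
            raise ValueError(
                f"censor mask length {ck.size} != {ts.n_volumes} volumes")
        keep = task_mask & ck
    if not keep.any():
        n_task = int(task_mask.sum())
        n_keep = int(np.asarray(censor.keep).sum()) if censor is not None else ts.n_volumes
        raise ValueError(
            f"no volumes retained: {n_task} task volumes, {n_keep} uncensored volumes, "
            "empty intersection")
    return ROITimeSeries(
        values=ts.values[:, keep],
        roi_names=list(ts.roi_names),
        tr_s=ts.tr_s,
        volume_index=ts.volume_index[keep],
        dropped_rois=list(ts.dropped_rois),
    )
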