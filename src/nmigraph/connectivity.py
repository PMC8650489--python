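"""Normalized mutual information (NMI) connectivity estimation.

Pairwise dependence between ROI time series is measured as the classical
mutual information of the two signals divided by the geometric mean of
their Shannon entropies, which rescales it to [0, 1]: 0 for statistical
independence, 1 for a deterministic (identical-binning) relationship.
Unlike Pearson correlation the coefficient is non-negative, so it can be
used directly as an edge weight of a weighted undirected graph.

All entropies are plug-in estimates from equal-width histograms over each
series' own observed range.  The whole-matrix builder is algebraically
identical to calling :func:`nmi_coefficient` on every unordered pair but
computes all joint histograms in one matrix product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DependenceEstimate",
    "ConnectivityMatrix",
    "default_bins",
    "shannon_entropy",
    "mutual_information",
    "nmi_coefficient",
    "build_connectivity_matrix",
]


def default_bins(n_samples: int) -> int:
    """Default histogram bin count: ceil(sqrt(n)) equal-width bins."""
    return int(math.ceil(math.sqrt(n_samples)))


@dataclass(frozen=True)
class DependenceEstimate:
    """NMI of one signal pair together with its entropy ingredients (nats)."""

    h_x: float
    h_y: float
    mi: float
    nmi: float
    n_bins: int
    n_samples: int
    degenerate: bool = False  # True when a constant series forced nmi := 0


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI matrix of NMI weights with a fixed zero diagonal."""

    weights: np.ndarray
    roi_names: list[str]
    n_bins: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if len(self.roi_names) != w.shape[0]:
            raise ValueError("roi_names length does not match matrix size")
        self.weights = w

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


def _validate_series(x: np.ndarray, name: str = "x") -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"{name} must have length >= 2, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    return x


def _bin_indices(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bin index of each sample over [min(x), max(x)].

    The maximum maps into the last bin (right-closed top bin), matching the
    usual histogram convention.  A constant series occupies bin 0 only.
    """
    lo = x.min()
    hi = x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=np.int64)
    idx = np.floor((x - lo) * (n_bins / (hi - lo))).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = np.sort(counts[counts > 0]) / n  # sorted so the sum is order-invariant
    return float(-np.sum(p * np.log(p)))


def shannon_entropy(x: np.ndarray, n_bins: int) -> float:
    """Plug-in Shannon entropy (nats) of the equal-width histogram of ``x``.

    H = -sum p log p with 0 log 0 := 0; a constant series has entropy 0.
    """
    x = _validate_series(x)
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    idx = _bin_indices(x, n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    return _entropy_from_counts(counts)


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int) -> float:
    """Histogram mutual information I(X;Y) = H(X) + H(Y) - H(X,Y), in nats.

    The joint histogram is n_bins x n_bins with each axis binned over that
    series' own range.  The result is clamped to be non-negative (plug-in
    MI can go fractionally below zero through rounding).
    """
    x = _validate_series(x, "x")
    y = _validate_series(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    xi = _bin_indices(x, n_bins)
    yi = _bin_indices(y, n_bins)
    joint = np.bincount(xi * n_bins + yi, minlength=n_bins * n_bins)
    h_x = _entropy_from_counts(np.bincount(xi, minlength=n_bins))
    h_y = _entropy_from_counts(np.bincount(yi, minlength=n_bins))
    h_xy = _entropy_from_counts(joint)
    return max(h_x + h_y - h_xy, 0.0)


def nmi_coefficient(x: np.ndarray, y: np.ndarray, n_bins: int | None = None) -> DependenceEstimate:
    """NMI of two series: mi / sqrt(h_x * h_y), clamped into [0, 1].

    A constant series has zero entropy; the coefficient is then defined as
    0 and flagged ``degenerate`` (a flat signal carries no information).
    """
    x = _validate_series(x, "x")
    y = _validate_series(y, "y")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if n_bins is None:
        n_bins = default_bins(x.size)
    xi = _bin_indices(x, n_bins)
    yi = _bin_indices(y, n_bins)
    h_x = _entropy_from_counts(np.bincount(xi, minlength=n_bins))
    h_y = _entropy_from_counts(np.bincount(yi, minlength=n_bins))
    joint = np.bincount(xi * n_bins + yi, minlength=n_bins * n_bins)
    mi = max(h_x + h_y - _entropy_from_counts(joint), 0.0)
    if h_x <= 0.0 or h_y <= 0.0:
        return DependenceEstimate(h_x, h_y, mi, 0.0, n_bins, x.size, degenerate=True)
    nmi = mi / math.sqrt(h_x * h_y)
    nmi = min(max(nmi, 0.0), 1.0)
    return DependenceEstimate(h_x, h_y, mi, nmi, n_bins, x.size)


def build_connectivity_matrix(ts, n_bins: int | None = None) -> ConnectivityMatrix:
    """Whole-brain NMI matrix from an ROI time-series container.

    Parameters
    ----------
    ts
        Object with ``values`` (ROI x volume array) and ``roi_names``;
        typically a :class:`nmigraph.signals.ROITimeSeries` restricted to
        the retained task volumes.
    n_bins
        Histogram bins per axis; default ceil(sqrt(n_volumes)).

    Entry (i, j) equals ``nmi_coefficient(values[i], values[j], n_bins)``;
    the diagonal is fixed to 0 so graphs built from the matrix are simple.

    Implementation: each ROI's bin indicator matrix is stacked so that all
    pairwise joint histograms come out of a single (R*b) x (R*b) integer
    matrix product; counts are exact, hence the matrix is exactly symmetric.
    """
    values = np.asarray(ts.values, dtype=float)
    names = list(ts.roi_names)
    n_rois, n_vol = values.shape
    if n_rois < 2:
        raise ValueError(f"need >= 2 ROIs, got {n_rois}")
    if n_vol < 2:
        raise ValueError(f"need >= 2 retained volumes, got {n_vol}")
    if not np.all(np.isfinite(values)):
        raise ValueError("time series contain non-finite values")
    if n_bins is None:
        n_bins = default_bins(n_vol)

    # indicator tensor: one-hot bin membership per ROI and volume
    idx = np.empty((n_rois, n_vol), dtype=np.int64)
    for r in range(n_rois):
        idx[r] = _bin_indices(values[r], n_bins)
    onehot = np.zeros((n_rois, n_bins, n_vol), dtype=np.float64)
    rows = np.repeat(np.arange(n_rois), n_vol)
    onehot[rows, idx.ravel(), np.tile(np.arange(n_vol), n_rois)] = 1.0

    flat = onehot.reshape(n_rois * n_bins, n_vol)
    joint = flat @ flat.T  # exact integer counts in float64

    marg = onehot.sum(axis=2)  # (R, b) marginal counts
    with np.errstate(divide="ignore", invalid="ignore"):
        p = marg / n_vol
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)  # (R,)
        pj = joint / n_vol
        plogp = np.where(pj > 0, pj * np.log(pj), 0.0)
    h_joint = -plogp.reshape(n_rois, n_bins, n_rois, n_bins).sum(axis=(1, 3))

    mi = h[:, None] + h[None, :] - h_joint
    np.maximum(mi, 0.0, out=mi)
    denom = np.sqrt(np.outer(h, h))
    with np.errstate(divide="ignore", invalid="ignore"):
        nmi = np.where(denom > 0, mi / denom, 0.0)
    np.clip(nmi, 0.0, 1.0, out=nmi)
    nmi = (nmi + nmi.T) / 2.0  # guard against summation-order asymmetry
    np.fill_diagonal(nmi, 0.0)
    return ConnectivityMatrix(weights=nmi, roi_names=names, n_bins=n_bins)
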