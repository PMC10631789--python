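"""Functional connectivity matrices and motion quality control.

Builds zero-lag Pearson correlation matrices from ROI time series, applies
the Fisher z transform, proportionally thresholds to a fixed fraction of the
strongest positive edges, and computes framewise displacement (FD) / DVARS
motion metrics with the exclusion rule maxFD > 3 mm or DVARS outliers in
more than 10% of frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ConnectivityMatrix",
    "QCMetrics",
    "DEFAULT_THRESHOLD_GRID",
    "correlation_matrix",
    "fisher_z",
    "proportional_threshold",
    "framewise_displacement",
    "dvars_series",
    "qc_metrics",
]

#: proportional-threshold grid: 0.20 to 0.50 in steps of 0.05 (seven entries)
DEFAULT_THRESHOLD_GRID = (0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)

FD_EXCLUSION_MM = 3.0
DVARS_OUTLIER_MAX_FRACTION = 0.10
ROTATION_SPHERE_RADIUS_MM = 50.0


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative edge-weight matrix with processing-state flags."""

    values: np.ndarray
    state: str  # raw_r | fisher_z
    threshold_p: float | None = None
    binarized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity values must be a square matrix")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly 0")
        if np.any(v < 0):
            raise ValueError("negative weights must be removed before constructing")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def correlation_matrix(ts: np.ndarray) -> ConnectivityMatrix:
    """Zero-lag Pearson correlation matrix of a T x N time-series array.

    The diagonal is zeroed and negative correlations are removed (set to 0),
    matching the cleaning applied before segregation analysis.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D (timepoints x ROIs) array")
    t, n = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 timepoints, got {t}")
    bad = np.flatnonzero(np.ptp(ts, axis=0) == 0)
    if bad.size:
        raise ValueError(f"constant-valued ROI column(s): {bad.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 0.0)
    r[r < 0] = 0.0
    return ConnectivityMatrix(r, state="raw_r")


def fisher_z(cm: ConnectivityMatrix, r_max: float | None = None) -> ConnectivityMatrix:
    """Elementwise Fisher z (atanh) transform of a raw correlation matrix.

    Entries at 1 (duplicated signals) diverge under atanh; supply ``r_max``
    to clip them first, otherwise such entries raise.
    """
    if cm.state != "raw_r":
        raise ValueError(f"fisher_z expects state 'raw_r', got {cm.state!r}")
    v = cm.values.copy()
    if np.any(v >= 1.0):
        if r_max is None:
            raise ValueError("correlation entries >= 1 present; pass r_max to clip")
        if not 0 < r_max < 1:
            raise ValueError("r_max must lie in (0, 1)")
        v = np.minimum(v, r_max)
    z = np.arctanh(v)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, state="fisher_z")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def proportional_threshold(
    cm: ConnectivityMatrix, p: float, binarize: bool = False
) -> ConnectivityMatrix:
    """Keep the fraction ``p`` of strongest edges; zero the rest.

    The retained edge count is round(p * N(N-1)/2) (half away from zero),
    capped by the number of positive edges available.  Ties are broken by
    ascending node-index pair so the survivor set is deterministic and
    nested across increasing ``p``.  With ``binarize`` survivors become 1.
    """
    if not 0 < p <= 1:
        raise ValueError(f"threshold proportion must be in (0, 1], got {p}")
    v = cm.values
    n = v.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = v[iu, ju]
    k = _round_half_away(p * n * (n - 1) / 2)
    pos = np.flatnonzero(w > 0)
    # sort positive edges by descending weight, then (i, j) ascending
    order = pos[np.lexsort((ju[pos], iu[pos], -w[pos]))]
    keep = order[: min(k, order.size)]
    out = np.zeros_like(v)
    out[iu[keep], ju[keep]] = 1.0 if binarize else w[keep]
    out = out + out.T
    return ConnectivityMatrix(
        out, state=cm.state, threshold_p=p, binarized=binarize
    )


def framewise_displacement(
    motion: np.ndarray, radius_mm: float = ROTATION_SPHERE_RADIUS_MM
) -> np.ndarray:
    """FD per frame from a T x 6 motion table (3 translations mm, 3 rotations rad).

    FD_t = sum of absolute backward differences, rotations converted to arc
    length on a sphere of ``radius_mm``.  Length T-1.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must be T x 6")
    d = np.abs(np.diff(motion, axis=0))
    return d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)


def dvars_series(ts: np.ndarray) -> np.ndarray:
    """Root-mean-square across ROIs of the backward temporal difference."""
    ts = np.asarray(ts, dtype=float)
    d = np.diff(ts, axis=0)
    return np.sqrt(np.mean(d**2, axis=1))


@dataclass
class QCMetrics:
    max_fd: float
    dvars: np.ndarray
    dvars_outlier_fraction: float
    excluded: bool


def qc_metrics(motion: np.ndarray, ts: np.ndarray) -> QCMetrics:
    """Motion QC for one scan; applies the exclusion rule.

    Excluded iff max FD > 3 mm or DVARS outlier frames (DVARS above
    median + 1.5 IQR) exceed 10% of frames.
    """
    motion = np.asarray(motion, dtype=float)
    ts = np.asarray(ts, dtype=float)
    if motion.shape[0] != ts.shape[0]:
        raise ValueError(
            f"motion rows ({motion.shape[0]}) must match timepoints ({ts.shape[0]})"
        )
    fd = framewise_displacement(motion)
    max_fd = float(fd.max()) if fd.size else 0.0
    dv = dvars_series(ts)
    if dv.size:
        q25, med, q75 = np.percentile(dv, [25, 50, 75])
        cut = med + 1.5 * (q75 - q25)
        frac = float(np.mean(dv > cut))
    else:
        frac = 0.0
    excluded = max_fd > FD_EXCLUSION_MM or frac > DVARS_OUTLIER_MAX_FRACTION
    return QCMetrics(max_fd, dv, frac, excluded)
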