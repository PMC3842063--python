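"""Boundary-quality metrics: mean perpendicular deviation and curve measure.

``acc_mean`` measures localization: each extracted point is dropped
perpendicularly onto the line through its two nearest ground-truth points
and the distances are averaged.  The curve measure sums squared first and
second finite differences along a polyline (stretchiness plus curvature);
comparing extracted and ground-truth curve measures quantifies jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


def point_line_distance(p_e, g1, g2) -> float:
    """Perpendicular distance from ``p_e`` to the infinite line through g1, g2.

    Uses the slope-free form |dx*(y_e - y1) - dy*(x_e - x1)| / hypot(dx, dy),
    which is algebraically equivalent to the slope-intercept formula where
    the slope exists and remains defined for vertical lines.
    """
    (y1, x1), (y2, x2) = np.asarray(g1, float), np.asarray(g2, float)
    ye, xe = np.asarray(p_e, float)
    dx, dy = x2 - x1, y2 - y1
    norm = np.hypot(dx, dy)
    if norm == 0:
        raise ValueError("the two ground-truth points coincide; line undefined")
    return float(abs(dx * (ye - y1) - dy * (xe - x1)) / norm)


def _two_nearest(distances: np.ndarray, gt: np.ndarray) -> tuple[int, int]:
    """Indices of the two nearest distinct-position gt points.

    Ties for the second point prefer a gt-order neighbor of the first, so
    the local line is the one between adjacent ground-truth points.
    """
    k = int(np.argmin(distances))
    allowed = ~(gt == gt[k]).all(axis=1)
    if not allowed.any():
        raise ValueError("ground truth is degenerate (all points identical)")
    d2 = distances[allowed].min()
    ties = np.flatnonzero(allowed & (distances == d2))
    for neighbor in (k - 1, k + 1):
        if neighbor in ties:
            return k, neighbor
    return k, int(ties[0])


def acc_mean(extracted: np.ndarray, gt: np.ndarray) -> float:
    """Mean perpendicular deviation of extracted points from the gt polyline.

    Asymmetric in its arguments by definition: deviations are measured
    from each *extracted* point to the local ground-truth line.
    """
    ext = np.asarray(extracted, dtype=np.float64)
    gtp = np.asarray(gt, dtype=np.float64)
    if ext.ndim != 2 or ext.shape[0] < 1:
        raise ValueError("extracted boundary must be non-empty")
    if gtp.ndim != 2 or gtp.shape[0] < 2:
        raise ValueError("ground truth needs at least 2 points")
    dmat = cdist(ext, gtp)
    total = 0.0
    for j in range(len(ext)):
        k, k1 = _two_nearest(dmat[j], gtp)
        total += point_line_distance(ext[j], gtp[k], gtp[k1])
    return total / len(ext)


def curve_measure(boundary: np.ndarray) -> float:
    """Sum over interior points of squared first plus second difference norms."""
    pts = np.asarray(boundary, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("curve measure needs at least 3 points")
    d = pts[1:] - pts[:-1]            # d[j-1] = p_j - p_{j-1}
    dd = pts[:-2] - 2 * pts[1:-1] + pts[2:]
    first = (d[:-1] ** 2).sum()       # j = 2..m-1
    second = (dd ** 2).sum()
    return float(first + second)


@dataclass
class BoundaryComparison:
    acc_mean: float
    curve_extracted: float
    curve_gt: float

    @property
    def curve_diff(self) -> float:
        return abs(self.curve_extracted - self.curve_gt)

    def as_dict(self) -> dict[str, float]:
        return {
            "acc_mean": self.acc_mean,
            "curve_extracted": self.curve_extracted,
            "curve_gt": self.curve_gt,
            "curve_diff": self.curve_diff,
        }


def compare(extracted: np.ndarray, gt: np.ndarray) -> BoundaryComparison:
    """Assemble acc_mean, both curve measures and their absolute difference."""
    return BoundaryComparison(
        acc_mean=acc_mean(extracted, gt),
        curve_extracted=curve_measure(extracted),
        curve_gt=curve_measure(gt),
    )


def aggregate(comparisons: list[BoundaryComparison]) -> dict[str, float]:
    """Mean and standard deviation of each metric across boundary pairs."""
    if not comparisons:
        raise ValueError("no comparisons to aggregate")
    out: dict[str, float] = {"n": float(len(comparisons))}
    for key in ("acc_mean", "curve_extracted", "curve_gt", "curve_diff"):
        values = np.array([c.as_dict()[key] for c in comparisons])
        out[f"{key}_mean"] = float(values.mean())
        out[f"{key}_std"] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return out
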