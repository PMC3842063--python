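"""Bivariate-Gaussian smoothness model over consecutive segment slopes.

Along a traced boundary P1..Pk, each step defines a segment whose
direction is summarized by atan2(dx, dy) with x = column and y = row (the
x-difference is the first argument throughout this package).  The pair
(newest segment angle, previous segment angle) collected over training
boundaries clusters tightly; a bivariate Gaussian fitted to that cloud
gives the conditional location density P(candidate | Pk, Pk-1) that keeps
the trace smooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) into (-pi, pi]."""
    return -((np.pi - np.asarray(theta)) % TWO_PI - np.pi)


def _segment_angles(points: np.ndarray) -> np.ndarray:
    """atan2(dcol, drow) of consecutive-point differences; errors on repeats."""
    pts = np.asarray(points, dtype=np.float64)
    diffs = pts[1:] - pts[:-1]
    repeated = np.flatnonzero((diffs == 0).all(axis=1))
    if repeated.size:
        raise ValueError(f"repeated consecutive boundary point at index {int(repeated[0]) + 1}")
    # (row, col) points; x = col, y = row; x-difference first, as printed.
    return np.arctan2(diffs[:, 1], diffs[:, 0])


def collect_slope_vectors(boundary: np.ndarray) -> np.ndarray:
    """Slope-pair vectors (theta_k, theta_{k-1}) for k = 3..n; shape (n-2, 2)."""
    pts = np.asarray(boundary)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("boundary must contain at least 3 points")
    theta = _segment_angles(pts)
    return np.column_stack([theta[1:], theta[:-1]])


@dataclass
class SmoothnessModel:
    """Mean and regularized covariance of the 2-D slope-pair distribution."""

    mean: np.ndarray         # (2,)
    covariance: np.ndarray   # (2, 2) symmetric positive-definite
    epsilon: float           # diagonal regularization that was added

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError("covariance must be positive-definite")


def fit_gaussian(slopes: np.ndarray, epsilon: float = 1e-6) -> SmoothnessModel:
    """Maximum-likelihood Gaussian fit (covariance divided by N) plus eps*I.

    The regularization keeps the covariance invertible for near-collinear
    training boundaries whose slope cloud is degenerate.
    """
    X = np.asarray(slopes, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 slope vectors in an (n, 2) array")
    mean = X.mean(axis=0)
    centered = X - mean
    cov = centered.T @ centered / X.shape[0]
    cov = cov + epsilon * np.eye(2)
    return SmoothnessModel(mean=mean, covariance=cov, epsilon=float(epsilon))


def _density(model: SmoothnessModel, x: np.ndarray) -> np.ndarray:
    # residuals are circular quantities: wrap into (-pi, pi] componentwise
    resid = wrap_angle(x - model.mean)
    inv = np.linalg.inv(model.covariance)
    det = np.linalg.det(model.covariance)
    quad = np.einsum("...i,ij,...j->...", resid, inv, resid)
    return np.exp(-0.5 * quad) / (TWO_PI * np.sqrt(det))


def slope_density(model: SmoothnessModel, slope_vector: np.ndarray) -> np.ndarray | float:
    """Gaussian density of slope-pair vector(s), angle-wrapped residuals."""
    x = np.asarray(slope_vector, dtype=np.float64)
    out = _density(model, x)
    return float(out) if x.ndim == 1 else out


def smoothness_probability(
    model: SmoothnessModel,
    candidate: tuple[int, int],
    p_k: tuple[int, int],
    p_k1: tuple[int, int],
) -> float:
    """Density of the slope pair formed with ``candidate`` as the newest point.

    x = (atan2(x_c - x_k, y_c - y_k), atan2(x_k - x_{k-1}, y_k - y_{k-1}))
    evaluated under the fitted bivariate Gaussian with the standard
    1/(2*pi*sqrt(|Sigma|)) normalizer.
    """
    pts = np.asarray([p_k1, p_k, candidate], dtype=np.float64)
    theta = _segment_angles(pts)  # raises on coincident points
    x = np.array([theta[1], theta[0]])
    return float(_density(model, x))


def candidate_slope_densities(
    model: SmoothnessModel,
    candidates: np.ndarray,
    p_k: tuple[int, int],
    p_k1: tuple[int, int],
) -> np.ndarray:
    """Vectorized :func:`smoothness_probability` over an (n, 2) candidate array."""
    cands = np.asarray(candidates, dtype=np.float64)
    prev = _segment_angles(np.asarray([p_k1, p_k], dtype=np.float64))[0]
    d = cands - np.asarray(p_k, dtype=np.float64)
    theta_new = np.arctan2(d[:, 1], d[:, 0])
    x = np.column_stack([theta_new, np.full(len(cands), prev)])
    return _density(model, x)


def save_text(model: SmoothnessModel) -> str:
    """Plain-text key/value serialization (full float precision)."""
    c = model.covariance
    lines = [
        f"mean {float(model.mean[0])!r} {float(model.mean[1])!r}",
        f"covariance {float(c[0, 0])!r} {float(c[0, 1])!r} "
        f"{float(c[1, 0])!r} {float(c[1, 1])!r}",
        f"epsilon {float(model.epsilon)!r}",
    ]
    return "\n".join(lines) + "\n"


def load_text(text: str) -> SmoothnessModel:
    fields: dict[str, list[float]] = {}
    for line in text.strip().splitlines():
        key, *vals = line.split()
        fields[key] = [float(v) for v in vals]
    return SmoothnessModel(
        mean=np.array(fields["mean"]),
        covariance=np.array(fields["covariance"]).reshape(2, 2),
        epsilon=fields["epsilon"][0],
    )
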