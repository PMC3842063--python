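"""Comparison baselines: a greedy active contour and a threshold extractor.

The snake minimizes image (external) plus shape (internal) energy by
moving each vertex within a small search window — the per-point greedy
movement of classic window-search snakes.  The threshold baseline stands
in for iterative threshold selection methods: Otsu threshold, largest
connected component, morphological closing, ordered outer-edge trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label
from skimage.morphology import closing, erosion


@dataclass
class SnakeConfig:
    alpha: float = 1.0
    beta: float = 0.0
    gamma: float = 0.0
    sigma: float = 3.0
    search_window: int = 7
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if self.search_window < 3 or self.search_window % 2 == 0:
            raise ValueError("search_window must be an odd integer >= 3")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("energy weights must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def external_energy(image: np.ndarray, sigma: float) -> np.ndarray:
    """Negative gradient magnitude of the Gaussian-smoothed image (<= 0)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    smoothed = gaussian_filter(np.asarray(image, dtype=np.float64), sigma)
    gr, gc = np.gradient(smoothed)
    return -np.hypot(gr, gc)


def _vertex_energy(p, prev_v, next_v, field, config) -> float:
    # NOTE: following the printed formulation, beta weights the squared
    # first difference (labeled "curvature" there) and gamma the squared
    # second difference (labeled "continuity") — the standard snake names
    # are the other way around.
    e = config.alpha * field[p[0], p[1]]
    if prev_v is not None:
        e += config.beta * float((p[0] - prev_v[0]) ** 2 + (p[1] - prev_v[1]) ** 2)
    if prev_v is not None and next_v is not None:
        dd0 = next_v[0] - 2 * p[0] + prev_v[0]
        dd1 = next_v[1] - 2 * p[1] + prev_v[1]
        e += config.gamma * float(dd0 ** 2 + dd1 ** 2)
    return float(e)


def snake_energy(contour: np.ndarray, field: np.ndarray, config: SnakeConfig) -> float:
    """Total contour energy: sum of external plus internal vertex terms."""
    pts = np.asarray(contour)
    total = 0.0
    for i, p in enumerate(pts):
        prev_v = pts[i - 1] if i > 0 else None
        next_v = pts[i + 1] if i < len(pts) - 1 else None
        total += _vertex_energy(p, prev_v, next_v, field, config)
    return total


def greedy_snake_step(
    contour: np.ndarray, field: np.ndarray, config: SnakeConfig
) -> tuple[np.ndarray, int]:
    """One greedy pass: each vertex moves to its window's minimum-energy spot.

    Vertices are visited in index order; neighbor positions are those of
    the previous iteration, stated for determinism.  A vertex moves only
    if a strictly lower energy is found (first minimum in row-major window
    order).  Returns the new contour and the number of vertices moved.
    """
    pts = np.asarray(contour, dtype=np.int64)
    if pts.ndim != 2 or len(pts) < 3:
        raise ValueError("contour needs at least 3 vertices")
    h, w = field.shape
    half = config.search_window // 2
    new_pts = pts.copy()
    moved = 0
    for i in range(len(pts)):
        prev_v = pts[i - 1] if i > 0 else None
        next_v = pts[i + 1] if i < len(pts) - 1 else None
        best = tuple(pts[i])
        best_e = _vertex_energy(best, prev_v, next_v, field, config)
        for dr in range(-half, half + 1):
            for dc in range(-half, half + 1):
                cand = (pts[i, 0] + dr, pts[i, 1] + dc)
                if not (0 <= cand[0] < h and 0 <= cand[1] < w):
                    continue
                e = _vertex_energy(cand, prev_v, next_v, field, config)
                if e < best_e:
                    best, best_e = cand, e
        if best != tuple(pts[i]):
            new_pts[i] = best
            moved += 1
    return new_pts, moved


def run_snake(
    image: np.ndarray, contour: np.ndarray, config: SnakeConfig | None = None
) -> np.ndarray:
    """Iterate greedy steps until no vertex moves or max_iterations."""
    config = config or SnakeConfig()
    field = external_energy(image, config.sigma)
    pts = np.asarray(contour, dtype=np.int64)
    for _ in range(config.max_iterations):
        pts, moved = greedy_snake_step(pts, field, config)
        if moved == 0:
            break
    return pts


def threshold_boundary(image: np.ndarray) -> np.ndarray:
    """Otsu + largest component + closing, then an ordered outer-edge trace.

    Returned points lie on the foreground side of the edge; runs of the
    component that coincide with the image border (which abut no
    background) are dropped.  Empty array if no foreground survives.
    """
    img = np.asarray(image)
    if np.ptp(img) == 0:
        return np.empty((0, 2), dtype=np.int64)
    mask = img > threshold_otsu(img)
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    labels = label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = closing(labels == largest, footprint=np.ones((3, 3)))
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)

    # edge pixels that actually touch background inside the image (padding
    # with True keeps image-border runs out of the edge set)
    padded = np.pad(mask, 1, constant_values=True)
    eroded = erosion(padded, footprint=np.ones((3, 3)))[1:-1, 1:-1]
    edge = mask & ~eroded

    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        return np.empty((0, 2), dtype=np.int64)
    longest = max(contours, key=len)
    ordered: list[tuple[int, int]] = []
    h, w = mask.shape
    for r, c in np.round(longest).astype(int):
        r, c = min(max(r, 0), h - 1), min(max(c, 0), w - 1)
        if edge[r, c] and (not ordered or ordered[-1] != (r, c)):
            ordered.append((r, c))
    if len(ordered) > 1 and ordered[0] == ordered[-1]:
        ordered.pop()
    return np.asarray(ordered, dtype=np.int64).reshape(-1, 2)
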