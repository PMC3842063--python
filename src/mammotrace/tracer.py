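"""Sequential probabilistic boundary tracing.

The trace starts at the topmost pixel classified as boundary texture and
grows one point at a time: all pixels within radius ``r`` of the current
point that the texture model classifies as boundary are scored by the
product of texture probability, slope-pair smoothness density, and the
Laplace sharpening prior (according to the configured mode), and the
maximum-score candidate is appended until no boundary-class candidate
remains, the trace reaches a new image border, or a step cap is hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import lbp, smoothness as sm
from .prior import PriorConfig, laplace_prior
from .texture import TextureModel, texture_probability

log = logging.getLogger(__name__)

MODES = ("T", "TS", "TSP")


@dataclass
class TraceConfig:
    window: int = 50
    radius: int = 20
    mode: str = "TSP"
    max_steps: int = 4000
    revisit_exclusion: int | None = None   # Chebyshev; defaults to radius // 2
    prior: PriorConfig = field(default_factory=PriorConfig)
    convention: str = "strict"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.radius < 2:
            raise ValueError("radius must be >= 2")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.revisit_exclusion is None:
            self.revisit_exclusion = self.radius // 2


@dataclass
class CandidateScore:
    point: tuple[int, int]
    texture_p: float
    smooth_p: float
    prior_p: float

    @property
    def joint(self) -> float:
        return self.texture_p * self.smooth_p * self.prior_p


@lru_cache(maxsize=8)
def _disk_offsets(radius: int) -> np.ndarray:
    """Row-major lattice offsets with 0 < distance <= radius."""
    span = np.arange(-radius, radius + 1)
    dr, dc = np.meshgrid(span, span, indexing="ij")
    d2 = dr**2 + dc**2
    keep = (d2 > 0) & (d2 <= radius**2)
    return np.column_stack([dr[keep], dc[keep]])


def candidate_points(
    current: tuple[int, int],
    previous: list[tuple[int, int]],
    image_shape: tuple[int, int],
    config: TraceConfig,
) -> np.ndarray:
    """In-image punctured-disk pixels around ``current``, minus revisit zones.

    Any pixel within ``revisit_exclusion`` (Chebyshev) of an already
    accepted point other than ``current`` is excluded; the zone supplies
    the forward bias of the trace without assuming an orientation.
    Returned in row-major order.
    """
    h, w = image_shape
    pts = np.asarray(current, dtype=np.int64) + _disk_offsets(config.radius)
    inside = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    pts = pts[inside]
    excl = config.revisit_exclusion
    relevant = [
        p for p in previous
        if tuple(p) != tuple(current)
        and max(abs(p[0] - current[0]), abs(p[1] - current[1])) <= config.radius + excl
    ]
    if relevant and len(pts):
        prev = np.asarray(relevant, dtype=np.int64)
        cheb = np.abs(pts[:, None, :] - prev[None, :, :]).max(axis=2)
        pts = pts[(cheb > excl).all(axis=1)]
    return pts


def score_candidate(
    candidate: tuple[int, int],
    p_k: tuple[int, int],
    p_k1: tuple[int, int] | None,
    descriptor: np.ndarray,
    texture_model: TextureModel,
    smoothness_model: sm.SmoothnessModel | None,
    config: TraceConfig,
) -> CandidateScore:
    """Joint score of one candidate; disabled/unavailable factors count as 1.

    The smoothness factor applies in TS/TSP modes once two history points
    exist; the prior applies in TSP mode.  Mode T reduces the joint score
    to the texture probability alone.
    """
    texture_p = float(texture_probability(texture_model, descriptor))
    smooth_p = 1.0
    if config.mode in ("TS", "TSP") and p_k1 is not None:
        if smoothness_model is None:
            raise ValueError("smoothness model required in TS/TSP modes")
        smooth_p = sm.smoothness_probability(smoothness_model, candidate, p_k, p_k1)
    prior_p = float(laplace_prior(texture_p, config.prior)) if config.mode == "TSP" else 1.0
    return CandidateScore(tuple(candidate), texture_p, smooth_p, prior_p)


def _row_probabilities(codes, model, row, width, window):
    centers = np.column_stack([np.full(width, row), np.arange(width)])
    desc = lbp.batch_descriptors(codes, centers, window)
    return np.asarray(texture_probability(model, desc))


def find_start_point(
    image: np.ndarray,
    model: TextureModel,
    window: int = 50,
    convention: str = "strict",
    _codes: np.ndarray | None = None,
) -> tuple[int, int] | None:
    """Topmost boundary-class pixel row; max-probability pixel in that row.

    The image is scanned top to bottom, left to right; in the first row
    containing any boundary-class pixel, the whole row is evaluated and
    the pixel of maximum texture probability is returned (leftmost on
    ties).  With no history the smoothness term marginalizes out and the
    prior is monotone in the texture probability, so ranking by texture
    probability alone is exact.  Returns None when no pixel classifies as
    boundary.
    """
    codes = _codes if _codes is not None else lbp.lbp_image(image, convention=convention)
    h, w = codes.shape
    for row in range(h):
        probs = _row_probabilities(codes, model, row, w, window)
        if (probs >= 0.5).any():
            return (row, int(np.argmax(probs)))
    return None


def _border_sides(point: tuple[int, int], shape: tuple[int, int]) -> set[str]:
    r, c = point
    h, w = shape
    sides = set()
    if r == 0:
        sides.add("top")
    if r == h - 1:
        sides.add("bottom")
    if c == 0:
        sides.add("left")
    if c == w - 1:
        sides.add("right")
    return sides


def trace_boundary(
    image: np.ndarray,
    texture_model: TextureModel,
    smoothness_model: sm.SmoothnessModel | None,
    config: TraceConfig | None = None,
) -> np.ndarray:
    """Trace the boundary of ``image``; returns an ordered (n, 2) point array.

    Terminates when no candidate classifies as boundary, when
    ``max_steps`` points have been accepted, or when an accepted point
    touches an image border side that the start point does not itself lie
    on (the start sits on the border whenever the boundary meets the image
    edge, so contact with a *new* side marks the far end of the curve).
    An empty array is returned (with a logged reason) if no start point
    exists.
    """
    config = config or TraceConfig()
    codes = lbp.lbp_image(image, convention=config.convention)
    start = find_start_point(image, texture_model, config.window,
                             convention=config.convention, _codes=codes)
    if start is None:
        log.info("trace aborted: no pixel classified as boundary texture")
        return np.empty((0, 2), dtype=np.int64)

    shape = image.shape
    start_sides = _border_sides(start, shape)
    accepted: list[tuple[int, int]] = [start]
    use_smooth = config.mode in ("TS", "TSP")
    use_prior = config.mode == "TSP"
    if use_smooth and smoothness_model is None:
        raise ValueError("smoothness model required in TS/TSP modes")

    while len(accepted) < config.max_steps:
        current = accepted[-1]
        cands = candidate_points(current, accepted, shape, config)
        if len(cands) == 0:
            log.info("trace ended: no candidates left after %d points", len(accepted))
            break
        desc = lbp.batch_descriptors(codes, cands, config.window)
        probs = np.asarray(texture_probability(texture_model, desc))
        keep = probs >= 0.5
        if not keep.any():
            log.info("trace ended: no boundary-class candidate after %d points", len(accepted))
            break
        cands, probs = cands[keep], probs[keep]

        joint = probs.copy()
        if use_smooth and len(accepted) >= 2:
            joint = joint * sm.candidate_slope_densities(
                smoothness_model, cands, current, accepted[-2])
        if use_prior:
            joint = joint * np.asarray(laplace_prior(probs, config.prior))

        best = int(np.argmax(joint))   # first maximum = row-major tie-break
        point = (int(cands[best, 0]), int(cands[best, 1]))
        accepted.append(point)
        new_sides = _border_sides(point, shape) - start_sides
        if new_sides:
            log.info("trace ended: reached image border (%s) after %d points",
                     ",".join(sorted(new_sides)), len(accepted))
            break
    return np.asarray(accepted, dtype=np.int64)
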