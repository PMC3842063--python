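"""Laplace sharpening prior on the texture probability.

The sigmoid at the core of SVM probability calibration has no sharp
transition near high probabilities, so two candidates with texture
probabilities 0.93 and 0.99 look almost equally good.  Evaluating the
lower branch of a Laplace density at the texture probability multiplies
the joint score by a factor growing as e per ``beta`` of probability,
which restores a strong preference for the highest-probability candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class PriorConfig:
    """Location ``mu`` and scale ``beta`` of the Laplace prior."""

    mu: float = 1.0
    beta: float = 0.05

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not 0 < self.mu <= 1:
            raise ValueError(f"mu must lie in (0, 1], got {self.mu}")


def laplace_prior(x: np.ndarray | float, config: PriorConfig | None = None) -> np.ndarray | float:
    """Lower-branch Laplace density exp(-(mu - x)/beta) / (2 beta).

    Strictly increasing in ``x`` on [0, mu]; peaks at 1/(2 beta) when
    x = mu.  Values above ``mu`` (possible only for user-supplied mu < 1)
    are clamped to ``mu`` and logged.
    """
    config = config or PriorConfig()
    arr = np.asarray(x, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("texture probability must lie in [0, 1]")
    if np.any(arr > config.mu):
        log.warning("texture probability above prior mu=%g; clamping", config.mu)
        arr = np.minimum(arr, config.mu)
    out = np.exp(-(config.mu - arr) / config.beta) / (2.0 * config.beta)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out
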