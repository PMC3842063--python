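"""High-level training / tracing / ablation pipelines used by the CLI."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import evaluation, smoothness as sm, texture
from .io import ModelArchive
from .prior import PriorConfig
from .tracer import TraceConfig, trace_boundary

log = logging.getLogger(__name__)


def train_archive(
    images: list[np.ndarray],
    boundaries: list[np.ndarray],
    window: int = 50,
    n_negatives_per_image: int = 900,
    exclusion_distance: int = texture.DEFAULT_EXCLUSION,
    folds: int = 5,
    grid: dict | None = None,
    seed: int = 0,
    max_per_class: int | None = None,
    prior: PriorConfig | None = None,
    convention: str = "strict",
) -> ModelArchive:
    """Collect samples, train the texture SVM, fit the slope Gaussian.

    ``max_per_class`` caps the per-class sample count fed to PCA and the
    grid search (seeded subsample), trading a little model quality for a
    large cut in SVM training and evaluation cost.
    """
    samples = texture.collect_training_samples(
        images, boundaries, window=window,
        n_negatives_per_image=n_negatives_per_image,
        exclusion_distance=exclusion_distance, seed=seed, convention=convention)
    if max_per_class is not None:
        samples = texture.subsample_samples(samples, max_per_class, seed=seed)
    tmodel = texture.train_texture_model(samples, folds=folds, grid=grid, seed=seed)
    slopes = np.vstack([sm.collect_slope_vectors(b) for b in boundaries])
    smodel = sm.fit_gaussian(slopes)
    return ModelArchive(
        texture=tmodel, smoothness=smodel, prior=prior or PriorConfig(),
        window=window, convention=convention)


def trace_with_archive(
    image: np.ndarray,
    archive: ModelArchive,
    mode: str = "TSP",
    radius: int = 20,
    max_steps: int = 4000,
    window: int | None = None,
) -> np.ndarray:
    """Trace one image with a model archive, enforcing config consistency."""
    if window is not None and window != archive.window:
        raise ValueError(
            f"archive was trained with window={archive.window}; "
            f"refusing to trace with window={window}")
    config = TraceConfig(window=archive.window, radius=radius, mode=mode,
                         max_steps=max_steps, prior=archive.prior,
                         convention=archive.convention)
    return trace_boundary(image, archive.texture, archive.smoothness, config)


def ablate(
    images: list[np.ndarray],
    gt_boundaries: list[np.ndarray],
    archive: ModelArchive,
    modes: tuple[str, ...] = ("T", "TS", "TSP"),
    radius: int = 20,
    max_steps: int = 4000,
) -> pd.DataFrame:
    """Run the tracer in each mode over a test set; per-image metric table.

    Rows are images, columns ``acc_mean_<mode>`` / ``curve_diff_<mode>``,
    with ``mean`` and ``std`` summary rows appended.
    """
    records: dict[str, dict[str, float]] = {}
    for i, (image, gt) in enumerate(zip(images, gt_boundaries)):
        row: dict[str, float] = {}
        for mode in modes:
            traced = trace_with_archive(image, archive, mode=mode,
                                        radius=radius, max_steps=max_steps)
            if len(traced) < 3:
                log.warning("image %d mode %s: trace too short (%d points)",
                            i, mode, len(traced))
                row[f"acc_mean_{mode}"] = np.nan
                row[f"curve_diff_{mode}"] = np.nan
                continue
            comp = evaluation.compare(traced, gt)
            row[f"acc_mean_{mode}"] = comp.acc_mean
            row[f"curve_diff_{mode}"] = comp.curve_diff
        records[f"image_{i:03d}"] = row
    table = pd.DataFrame.from_dict(records, orient="index")
    table.loc["mean"] = table.mean()
    table.loc["std"] = table.iloc[:-1].std()
    return table
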