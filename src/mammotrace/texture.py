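"""Boundary/non-boundary texture classification with calibrated probabilities.

Training samples pair window descriptors with binary labels: positives are
ground-truth boundary pixels together with their immediate left and right
neighbors; negatives are random pixels drawn away from the boundary.  An
RBF-kernel SVM (hyperparameters from a logarithmic grid search under
stratified 5-fold cross-validation) separates the classes in PCA space,
and a sigmoid fitted to the decision values turns the margin distance
into P(boundary | descriptor) — the two-class case of pairwise-coupling
probability estimation, where the coupling optimization is trivial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_cdt
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from . import lbp

log = logging.getLogger(__name__)

BOUNDARY = "boundary"
NONBOUNDARY = "nonboundary"

#: default logarithmic hyperparameter grid (cost 2^-5..2^15, width 2^-15..2^3,
#: both stepped by a factor of 4)
DEFAULT_GRID: dict[str, np.ndarray] = {
    "C": 2.0 ** np.arange(-5, 16, 2),
    "gamma": 2.0 ** np.arange(-15, 4, 2),
}

#: coarser grid (factor-16 steps) for runs where training time matters more
#: than the last fraction of a percent of CV accuracy
COARSE_GRID: dict[str, np.ndarray] = {
    "C": 2.0 ** np.arange(-5, 16, 4),
    "gamma": 2.0 ** np.arange(-15, 4, 4),
}

#: default Chebyshev exclusion distance for negatives.  Discarding only
#: pixels on or just beyond the textured transition band keeps the
#: near-boundary hard negatives; excluding everything within a half
#: window would leave the classifier with no evidence that windows a few
#: pixels off the skin line are negatives, widening its boundary corridor
#: and bounding tracer localization.
DEFAULT_EXCLUSION = 10


@dataclass
class LabeledSample:
    descriptor: np.ndarray
    label: str                     # BOUNDARY or NONBOUNDARY
    source_image: str
    location: tuple[int, int]      # (row, col)

    def __post_init__(self) -> None:
        if self.label not in (BOUNDARY, NONBOUNDARY):
            raise ValueError(f"label must be {BOUNDARY!r} or {NONBOUNDARY!r}")


def collect_training_samples(
    images: list[np.ndarray],
    gt_boundaries: list[np.ndarray],
    window: int = 50,
    n_negatives_per_image: int = 900,
    exclusion_distance: int = DEFAULT_EXCLUSION,
    seed: int = 0,
    convention: str = "strict",
    image_ids: list[str] | None = None,
) -> list[LabeledSample]:
    """Build the labeled descriptor set from images and ground-truth curves.

    Positives: every ground-truth boundary pixel plus its immediate left
    and right neighbors, deduplicated (and clipped to the image).
    Negatives: uniform random pixels, rejecting and resampling any within
    ``exclusion_distance`` (Chebyshev) of the boundary until exactly
    ``n_negatives_per_image`` are accepted per image.
    """
    if len(images) != len(gt_boundaries):
        raise ValueError("images and gt_boundaries must have equal length")
    if image_ids is None:
        image_ids = [f"image_{i:03d}" for i in range(len(images))]
    rng = np.random.default_rng(seed)
    samples: list[LabeledSample] = []
    for image, boundary, image_id in zip(images, gt_boundaries, image_ids):
        boundary = np.asarray(boundary)
        if boundary.ndim != 2 or boundary.shape[0] == 0:
            raise ValueError(f"{image_id}: ground-truth boundary is empty")
        h, w = image.shape
        codes = lbp.lbp_image(image, convention=convention)

        positive_locs: dict[tuple[int, int], None] = {}
        for r, c in boundary:
            for cc in (c - 1, c, c + 1):
                if 0 <= r < h and 0 <= cc < w:
                    positive_locs[(int(r), int(cc))] = None
        pos = np.array(list(positive_locs), dtype=np.intp)

        mask = np.ones((h, w), dtype=bool)
        mask[boundary[:, 0], boundary[:, 1]] = False
        cheb = distance_transform_cdt(mask, metric="chessboard")
        allowed = cheb > exclusion_distance
        if not allowed.any():
            raise ValueError(f"{image_id}: exclusion region covers the whole image")
        neg_locs: list[tuple[int, int]] = []
        for _ in range(200):  # bounded retries
            need = n_negatives_per_image - len(neg_locs)
            if need <= 0:
                break
            rows = rng.integers(0, h, size=4 * need)
            cols = rng.integers(0, w, size=4 * need)
            ok = allowed[rows, cols]
            neg_locs.extend(zip(rows[ok].tolist(), cols[ok].tolist()))
        else:
            raise ValueError(f"{image_id}: could not accept enough negatives")
        neg = np.array(neg_locs[:n_negatives_per_image], dtype=np.intp)

        pos_desc = lbp.batch_descriptors(codes, pos, window)
        neg_desc = lbp.batch_descriptors(codes, neg, window)
        samples.extend(
            LabeledSample(d, BOUNDARY, image_id, (int(r), int(c)))
            for d, (r, c) in zip(pos_desc, pos)
        )
        samples.extend(
            LabeledSample(d, NONBOUNDARY, image_id, (int(r), int(c)))
            for d, (r, c) in zip(neg_desc, neg)
        )
    return samples


def subsample_samples(
    samples: list[LabeledSample], max_per_class: int, seed: int = 0
) -> list[LabeledSample]:
    """Seeded per-class subsample, preserving original order."""
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for label in (BOUNDARY, NONBOUNDARY):
        idx = [i for i, s in enumerate(samples) if s.label == label]
        if len(idx) > max_per_class:
            idx = rng.choice(idx, size=max_per_class, replace=False).tolist()
        keep.extend(idx)
    return [samples[i] for i in sorted(keep)]


@dataclass
class TextureModel:
    """PCA basis + binary RBF SVM + sigmoid probability calibration."""

    pca: lbp.PCABasis
    svm: SVC
    calibration_slope: float
    calibration_intercept: float
    cv_config: dict = field(default_factory=dict)

    # Decision-function ingredients, exposed for inspection: f(x) =
    # sum_i alpha_i exp(-gamma ||x_i - x||^2) + b over the support centers.
    @property
    def support_centers(self) -> np.ndarray:
        return self.svm.support_vectors_

    @property
    def weights(self) -> np.ndarray:
        return self.svm.dual_coef_[0]

    @property
    def bias(self) -> float:
        return float(self.svm.intercept_[0])

    @property
    def kernel_width(self) -> float:
        gamma = self.svm.gamma
        return float(gamma) if not isinstance(gamma, str) else float(self.svm._gamma)


def train_texture_model(
    samples: list[LabeledSample],
    folds: int = 5,
    grid: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> TextureModel:
    """Fit PCA (0.99 rule), grid-searched RBF SVM, and sigmoid calibration.

    Hyperparameters maximize mean CV accuracy over the logarithmic grid
    (ties resolved by grid order); the calibration is a logistic
    regression on the decision values, so the returned probability is a
    strictly monotone function of the SVM margin.
    """
    labels = np.array([s.label for s in samples])
    if set(labels) != {BOUNDARY, NONBOUNDARY}:
        raise ValueError("training data must contain both classes")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    grid = grid if grid is not None else DEFAULT_GRID

    X_raw = np.stack([np.asarray(s.descriptor, dtype=np.float64) for s in samples])
    y = (labels == BOUNDARY).astype(int)   # class 1 = boundary, so the
    # positive side of the decision function is the boundary class

    basis = lbp.fit_pca(X_raw)
    X = lbp.project(basis, X_raw)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="rbf", cache_size=500),
        param_grid={k: np.asarray(v) for k, v in grid.items()},
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
    )
    search.fit(X, y)
    svm = search.best_estimator_

    f = svm.decision_function(X)
    calib = LogisticRegression(C=1.0)
    calib.fit(f[:, None], y)
    slope = float(calib.coef_[0, 0])
    intercept = float(calib.intercept_[0])
    if slope <= 0:
        log.warning("calibration slope %g is not positive; probabilities will "
                    "not increase with the decision value", slope)

    log.info("texture model: %d samples, %d PCA dims, CV accuracy %.4f, params %s",
             len(samples), basis.n_retained, search.best_score_, search.best_params_)
    return TextureModel(
        pca=basis,
        svm=svm,
        calibration_slope=slope,
        calibration_intercept=intercept,
        cv_config={
            "folds": folds,
            "grid": {k: np.asarray(v).tolist() for k, v in grid.items()},
            "best_params": {k: float(v) for k, v in search.best_params_.items()},
            "best_cv_accuracy": float(search.best_score_),
            "seed": seed,
        },
    )


def decision_values(model: TextureModel, descriptors: np.ndarray) -> np.ndarray:
    """SVM decision values f(x) for raw descriptor(s)."""
    X = np.asarray(descriptors, dtype=np.float64)
    single = X.ndim == 1
    Z = lbp.project(model.pca, X)
    f = model.svm.decision_function(Z[None, :] if single else Z)
    return f[0] if single else f


def texture_probability(model: TextureModel, descriptor: np.ndarray) -> np.ndarray | float:
    """Calibrated P(boundary | descriptor); sigmoid of the decision value."""
    f = decision_values(model, descriptor)
    p = 1.0 / (1.0 + np.exp(-(model.calibration_slope * f + model.calibration_intercept)))
    return float(p) if np.ndim(f) == 0 else p


def classify(model: TextureModel, descriptor: np.ndarray):
    """Boundary iff the calibrated probability is >= 0.5 (ties to boundary)."""
    p = texture_probability(model, descriptor)
    if np.ndim(p) == 0:
        return BOUNDARY if p >= 0.5 else NONBOUNDARY
    return np.where(p >= 0.5, BOUNDARY, NONBOUNDARY)
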