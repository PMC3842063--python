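"""Local binary pattern features for boundary-texture description.

An LBP code encodes, for each pixel, which of its eight neighbors are
brighter than it.  A texture patch is described by splitting a square
window into four equal quadrants and concatenating the four 256-bin code
histograms (1024 values), optionally projected onto a PCA basis retaining
more than 99% of the training variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

# Neighbor offsets, clockwise starting at the top-left neighbor.  Bit i-1
# (weight 2**(i-1)) corresponds to the i-th neighbor in this order.  Any
# fixed order works as long as training and tracing share it.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)

#: comparison conventions for the sign function applied to (neighbor - center)
#: "strict"  : bit set iff neighbor - center >= 1 (neighbor strictly greater)
#: "standard": bit set iff neighbor - center >= 0 (the common LBP convention)
LBP_CONVENTIONS = ("strict", "standard")

PCA_VARIANCE_FRACTION = 0.99


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"expected a non-empty 2-D grayscale image, got shape {image.shape}")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("image intensities must lie in [0, 255]")
    return image


def lbp_value(neighborhood: np.ndarray, convention: str = "strict") -> int:
    """LBP code of the center pixel of a 3x3 intensity patch.

    The code is sum_i 2**(i-1) * delta(z_i - z_0) over the eight neighbors
    z_1..z_8 taken clockwise from the top-left, where delta(u) = 1 iff
    u >= 1 under the default ``strict`` convention (u >= 0 under
    ``standard``).
    """
    patch = np.asarray(neighborhood)
    if patch.shape != (3, 3):
        raise ValueError(f"neighborhood must be 3x3, got shape {patch.shape}")
    if patch.min() < 0 or patch.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    if convention not in LBP_CONVENTIONS:
        raise ValueError(f"unknown LBP convention {convention!r}")
    center = int(patch[1, 1])
    code = 0
    for bit, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        diff = int(patch[1 + dr, 1 + dc]) - center
        if diff >= (1 if convention == "strict" else 0):
            code |= 1 << bit
    return code


def lbp_image(image: np.ndarray, convention: str = "strict") -> np.ndarray:
    """Per-pixel LBP codes of an image (same shape, dtype uint8).

    Border pixels are handled by replicate-padding the image by one pixel,
    so every pixel (the full image is scanned during initialization) has a
    defined code.
    """
    image = _check_image(image)
    if convention not in LBP_CONVENTIONS:
        raise ValueError(f"unknown LBP convention {convention!r}")
    padded = np.pad(image.astype(np.int16), 1, mode="edge")
    h, w = image.shape
    center = padded[1:1 + h, 1:1 + w]
    threshold = 1 if convention == "strict" else 0
    codes = np.zeros((h, w), dtype=np.uint8)
    for bit, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        neighbor = padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
        codes |= ((neighbor - center) >= threshold).astype(np.uint8) << bit
    return codes


def _window_bounds_padded(center: tuple[int, int], window: int) -> tuple[int, int]:
    # top-left of the window in coordinates of a map padded by window//2;
    # the center pixel sits at offset (window//2, window//2) of the window.
    half = window // 2
    return center[0], center[1]  # padded index of original (r, c) is (r+half, c+half)


def patch_descriptor(lbp_map: np.ndarray, center: tuple[int, int], window: int = 50) -> np.ndarray:
    """Concatenated 4-quadrant 256-bin histogram of a window of LBP codes.

    The ``window`` x ``window`` region centered on ``center`` (which sits at
    offset (window//2, window//2) from the window's top-left corner) is
    split into four equal quadrants (top-left, top-right, bottom-left,
    bottom-right); each contributes a 256-bin histogram of its codes and
    the four are concatenated into a length-1024 vector.  Windows reaching
    past the image bounds are clamped by edge replication.
    """
    descriptors = batch_descriptors(lbp_map, np.asarray([center]), window)
    return descriptors[0]


def batch_descriptors(lbp_map: np.ndarray, centers: np.ndarray, window: int = 50) -> np.ndarray:
    """Vectorized :func:`patch_descriptor` for many centers; (n, 1024) float32."""
    lbp_map = np.asarray(lbp_map)
    if lbp_map.ndim != 2 or lbp_map.size == 0:
        raise ValueError("lbp_map must be a non-empty 2-D array")
    if window < 2 or window % 2 != 0:
        raise ValueError(f"window must be an even integer >= 2, got {window}")
    centers = np.asarray(centers, dtype=np.intp)
    if centers.ndim != 2 or centers.shape[1] != 2:
        raise ValueError("centers must be an (n, 2) array of (row, col)")
    h, w = lbp_map.shape
    if centers.size and (
        centers[:, 0].min() < 0 or centers[:, 0].max() >= h
        or centers[:, 1].min() < 0 or centers[:, 1].max() >= w
    ):
        raise ValueError("window center outside the image")

    half = window // 2
    padded = np.pad(lbp_map, half, mode="edge")
    rows = centers[:, 0][:, None] + np.arange(window)[None, :]          # (n, window), padded coords
    cols = centers[:, 1][:, None] + np.arange(window)[None, :]
    windows = padded[rows[:, :, None], cols[:, None, :]]                # (n, window, window)

    q = half  # quadrant side
    n = len(centers)
    quads = np.empty((n, 4, q, q), dtype=windows.dtype)
    quads[:, 0] = windows[:, :q, :q]
    quads[:, 1] = windows[:, :q, q:]
    quads[:, 2] = windows[:, q:, :q]
    quads[:, 3] = windows[:, q:, q:]
    flat = quads.reshape(n * 4, q * q).astype(np.int64)
    block = (np.arange(n * 4)[:, None]) * 256
    counts = np.bincount((flat + block).ravel(), minlength=n * 4 * 256)
    return counts.reshape(n, 1024).astype(np.float32)


@dataclass
class PCABasis:
    """Orthonormal PCA basis retaining > 99% of the descriptor variance."""

    mean: np.ndarray          # (d,)
    components: np.ndarray    # (n_retained, d), orthonormal rows
    eigenvalues: np.ndarray   # all eigenvalues, descending
    n_retained: int

    @property
    def dim(self) -> int:
        return self.mean.shape[0]


def fit_pca(descriptors: np.ndarray, variance_fraction: float = PCA_VARIANCE_FRACTION) -> PCABasis:
    """Eigen-decompose the sample covariance of the descriptors.

    Retains the smallest number of leading components whose cumulative
    eigenvalue fraction exceeds ``variance_fraction`` (0.99 by default).
    """
    X = np.asarray(descriptors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 descriptors in an (n, d) array")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("descriptors have zero total variance; PCA is undefined")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    eigenvalues = pca.explained_variance_
    fractions = np.cumsum(eigenvalues) / eigenvalues.sum()
    n_retained = int(np.argmax(fractions > variance_fraction)) + 1
    return PCABasis(
        mean=pca.mean_.copy(),
        components=pca.components_[:n_retained].copy(),
        eigenvalues=eigenvalues.copy(),
        n_retained=n_retained,
    )


def project(basis: PCABasis, descriptor: np.ndarray) -> np.ndarray:
    """Project raw descriptor(s) onto the retained components."""
    X = np.asarray(descriptor, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != basis.dim:
        raise ValueError(f"descriptor length {X.shape[1]} does not match basis dimension {basis.dim}")
    Z = (X - basis.mean) @ basis.components.T
    return Z[0] if single else Z


def reconstruct(basis: PCABasis, projected: np.ndarray) -> np.ndarray:
    """Map projected coordinates back to descriptor space (lossy)."""
    Z = np.asarray(projected, dtype=np.float64)
    return Z @ basis.components + basis.mean


def save_descriptors(path, descriptors: np.ndarray, window: int,
                     convention: str = "strict") -> None:
    """Persist a raw descriptor matrix as a dense table with a header."""
    X = np.asarray(descriptors)
    header = f"mammotrace-descriptors dim={X.shape[1]} window={window} convention={convention}"
    np.savetxt(path, X, fmt="%g", header=header)


def load_descriptors(path) -> tuple[np.ndarray, dict]:
    """Read a descriptor table; returns (matrix, header metadata)."""
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("# mammotrace-descriptors"):
        raise ValueError(f"{path}: not a descriptor table")
    meta: dict = {}
    for token in first.split()[2:]:
        key, value = token.split("=")
        meta[key] = int(value) if value.isdigit() else value
    X = np.loadtxt(path, ndmin=2)
    if X.shape[1] != meta["dim"]:
        raise ValueError(f"{path}: header dim {meta['dim']} != data {X.shape[1]}")
    return X, meta
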