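"""Seeded mammogram-like phantom generator with exact ground truth.

Phantoms emulate the structure of an MLO-view mammogram: a near-black
noisy tape background on the right, a breast region on the left whose
interior brightens away from the skin line and carries correlated tissue
speckle, a darker textured transition band along the smooth open skin
boundary, and optionally a bright pectoral-muscle wedge in the top-left
corner plus a bright label rectangle in the background.  Every phantom
ships with its boundary polyline sampled at one-pixel row spacing, so
training, tracing, and evaluation run without any external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter


@dataclass
class PhantomConfig:
    size: tuple[int, int] = (512, 512)        # (height, width)
    background_mean: float = 5.0
    background_std: float = 2.0
    interior_peak: float = 180.0
    interior_edge: float = 40.0               # interior intensity at the skin line
    boundary_band_width: int = 15
    band_noise_std: float = 10.0              # speckle std of the boundary band
    texture_correlation_length: float = 4.0   # px, interior speckle granularity
    curve_control_points: int = 6
    curve_margin: float = 0.12      # top/bottom anchor column, fraction of width
    pectoral: bool = False
    label_artifact: bool = False
    noise_std: float = 2.0                    # global additive sensor noise
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.size
        if h < 32 or w < 32:
            raise ValueError("phantom must be at least 32x32")
        if not self.boundary_band_width < min(self.size) / 8:
            raise ValueError("boundary band too wide for the image size")
        if self.curve_control_points < 3:
            raise ValueError("need at least 3 curve control points")
        if not 0.02 <= self.curve_margin <= 0.6:
            raise ValueError("curve_margin must keep the curve inside the image")


@dataclass
class PhantomSample:
    image: np.ndarray                  # uint8 (h, w)
    gt_boundary: np.ndarray            # (h, 2) int, one point per row, top to bottom
    gt_pectoral: np.ndarray | None
    meta: PhantomConfig


def _speckle(rng: np.random.Generator, shape, correlation: float, std: float) -> np.ndarray:
    """Zero-mean correlated noise field with the requested pointwise std."""
    noise = gaussian_filter(rng.standard_normal(shape), correlation)
    return noise / noise.std() * std


def _boundary_curve(rng: np.random.Generator, config: PhantomConfig) -> np.ndarray:
    """Column of the skin line at each row: a smooth rightward bulge."""
    h, w = config.size
    n = config.curve_control_points
    rows = np.linspace(0, h - 1, n)
    t = rows / (h - 1)
    # rightward bulge anchored curve_margin from the left edge at top and
    # bottom.  Amplitude and jitter are sized so the skin line's
    # |dcol/drow| stays near or below 1: per-row integer sampling then
    # yields segment angles atan2(dcol, 1) in a tight cluster, the regime
    # the smoothness Gaussian assumes
    base = w * (config.curve_margin + 0.26 * np.sin(np.pi * t))
    jitter = rng.uniform(-1, 1, n) * 0.04 * w
    cols = np.clip(base + jitter, 2, w - 3)
    curve = PchipInterpolator(rows, cols)(np.arange(h))
    return np.clip(curve, 1, w - 2)


def generate_phantom(config: PhantomConfig | None = None) -> PhantomSample:
    """Render one phantom; bitwise deterministic for a given config."""
    config = config or PhantomConfig()
    rng = np.random.default_rng(config.seed)
    h, w = config.size

    curve = _boundary_curve(rng, config)                   # (h,)
    cols = np.arange(w)[None, :]
    signed = curve[:, None] - cols                         # >0 left of (inside) the curve

    # interior: ramp from the skin-line intensity toward the peak, with
    # multiplicative correlated tissue speckle
    ramp_length = 0.25 * w
    depth = np.clip(signed, 0, None)
    interior = config.interior_edge + (config.interior_peak - config.interior_edge) * (
        1.0 - np.exp(-depth / ramp_length))
    interior = interior * (1.0 + _speckle(rng, (h, w), config.texture_correlation_length, 0.06))

    background = config.background_mean + rng.normal(0, config.background_std, (h, w))

    # transition band: its own higher-variance, finer-grained speckle
    half_band = config.boundary_band_width / 2.0
    in_band = np.abs(signed) <= half_band
    t_band = np.clip((signed + half_band) / config.boundary_band_width, 0, 1)
    band = (config.background_mean
            + (config.interior_edge - config.background_mean) * t_band
            + _speckle(rng, (h, w), 2.0, config.band_noise_std))

    image = np.where(signed > half_band, interior,
                     np.where(signed < -half_band, background, band))

    gt_pectoral = None
    if config.pectoral:
        p0 = 0.8 * curve[0]                               # top-edge column of the wedge
        p1 = int(0.65 * h)                                # row where the wedge meets the left edge
        rows_all = np.arange(h)[:, None]
        wedge_col = p0 * (1.0 - rows_all / p1)
        in_wedge = (cols < wedge_col) & (signed > half_band)
        wedge_tex = 215.0 * (1.0 + _speckle(rng, (h, w), 3.0, 0.03))
        image = np.where(in_wedge, wedge_tex, image)
        pect_rows = np.arange(0, p1 + 1)
        pect_cols = np.round(p0 * (1.0 - pect_rows / p1)).astype(int)
        gt_pectoral = np.column_stack([pect_rows, np.clip(pect_cols, 0, w - 1)])

    if config.label_artifact:
        r0, c0 = int(0.08 * h), w - 90
        in_label = (np.arange(h)[:, None] >= r0) & (np.arange(h)[:, None] < r0 + 30) \
            & (cols >= c0) & (cols < c0 + 80) & (signed < -half_band)
        image = np.where(in_label, 235.0, image)

    image = image + rng.normal(0, config.noise_std, (h, w))
    image = np.clip(np.round(image), 0, 255).astype(np.uint8)

    gt = np.column_stack([np.arange(h), np.round(curve).astype(int)])
    return PhantomSample(image=image, gt_boundary=gt, gt_pectoral=gt_pectoral, meta=config)


def derive_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic, well-separated per-sample seeds from one master seed."""
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n)]


def generate_dataset(
    n_train: int,
    n_test: int,
    config: PhantomConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> dict:
    """Generate disjoint train/test phantoms; optionally write them to disk.

    The returned manifest dict records every parameter needed to
    regenerate the dataset bit for bit.  When ``out_dir`` is given, images
    are written as 8-bit PGM, boundaries as ``row,col`` CSV, and the
    manifest as JSON.
    """
    from . import io as mio  # deferred: io imports nothing from here

    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    config = config or PhantomConfig()
    seeds = derive_seeds(seed, n_train + n_test)
    manifest: dict = {
        "format_version": 1,
        "seed": seed,
        "config": {**asdict(config), "size": list(config.size)},
        "train": [], "test": [],
    }
    samples: dict[str, list[PhantomSample]] = {"train": [], "test": []}
    for split, count, offset in (("train", n_train, 0), ("test", n_test, n_train)):
        for i in range(count):
            cfg = PhantomConfig(**{**asdict(config), "seed": seeds[offset + i]})
            sample = generate_phantom(cfg)
            samples[split].append(sample)
            entry = {
                "image": f"{split}/phantom_{i:03d}.pgm",
                "boundary": f"{split}/phantom_{i:03d}_boundary.csv",
                "seed": seeds[offset + i],
            }
            if sample.gt_pectoral is not None:
                entry["pectoral"] = f"{split}/phantom_{i:03d}_pectoral.csv"
            manifest[split].append(entry)

    if out_dir is not None:
        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not overwrite:
            raise FileExistsError(f"output directory {out} is not empty")
        for split in ("train", "test"):
            (out / split).mkdir(parents=True, exist_ok=True)
            for entry, sample in zip(manifest[split], samples[split]):
                mio.write_image(sample.image, out / entry["image"])
                mio.write_boundary(sample.gt_boundary, out / entry["boundary"])
                if "pectoral" in entry:
                    mio.write_boundary(sample.gt_pectoral, out / entry["pectoral"])
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    manifest["samples"] = samples
    return manifest


def regenerate_from_manifest(manifest: dict) -> dict:
    """Rebuild the in-memory dataset recorded by a manifest."""
    config = dict(manifest["config"])
    config["size"] = tuple(config["size"])
    out: dict[str, list[PhantomSample]] = {"train": [], "test": []}
    for split in ("train", "test"):
        for entry in manifest[split]:
            cfg = PhantomConfig(**{**config, "seed": entry["seed"]})
            out[split].append(generate_phantom(cfg))
    return out
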