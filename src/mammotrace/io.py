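"""File formats and the combined model archive.

Images are 8-bit grayscale PGM (both the plain P2 and binary P5
encodings) or PNG.  Boundaries are ``row,col`` CSV files with 0-based
integer pixel coordinates, one point per line in trace order.  A trained
model travels as a single zip archive bundling the texture model
(PCA + SVM + calibration), the smoothness Gaussian as plain text, the
prior parameters and the feature configuration, with a format version
checked on load.
"""

from __future__ import annotations

import io as _stdio
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from PIL import Image, UnidentifiedImageError

from . import smoothness as sm
from .prior import PriorConfig
from .texture import TextureModel

FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """Raised for corrupt or version-incompatible model archives."""


def read_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale PGM (P2/P5) or PNG as a uint8 array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as img:
            if img.mode in ("RGB", "RGBA", "P"):
                raise ValueError(f"{path}: color images are not supported; "
                                 "convert to 8-bit grayscale first")
            if img.mode not in ("L", "1"):
                raise ValueError(f"{path}: unsupported bit depth (mode {img.mode}); "
                                 "only 8-bit grayscale is supported")
            return np.asarray(img.convert("L"), dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ValueError(f"{path}: not a recognized PGM/PNG image") from exc


def write_image(image: np.ndarray, path: str | Path, encoding: str = "binary") -> None:
    """Write a uint8 image; ``.pgm`` as P5 (or P2 with encoding='ascii')."""
    path = Path(path)
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("image intensities must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    if path.suffix.lower() == ".pgm" and encoding == "ascii":
        h, w = arr.shape
        rows = "\n".join(" ".join(map(str, row)) for row in arr)
        path.write_text(f"P2\n{w} {h}\n255\n{rows}\n")
        return
    Image.fromarray(arr, mode="L").save(path)


def read_boundary(path: str | Path) -> np.ndarray:
    """Read a ``row,col`` CSV boundary, preserving point order."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip().lower() != "row,col":
        raise ValueError(f"{path}: line 1: expected header 'row,col'")
    points: list[tuple[int, int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.strip().split(",")
        try:
            r, c = (int(p) for p in parts)
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: malformed row {line!r}") from exc
        if r < 0 or c < 0:
            raise ValueError(f"{path}: line {lineno}: negative coordinate")
        points.append((r, c))
    return np.asarray(points, dtype=np.int64).reshape(-1, 2)


def write_boundary(boundary: np.ndarray, path: str | Path) -> None:
    pts = np.asarray(boundary)
    lines = ["row,col"] + [f"{int(r)},{int(c)}" for r, c in pts]
    Path(path).write_text("\n".join(lines) + "\n")


def boundary_from_xy(points_xy: np.ndarray, one_based: bool = True) -> np.ndarray:
    """Convert (x, y) annotations (optionally 1-based) to (row, col) 0-based."""
    pts = np.asarray(points_xy, dtype=np.int64)
    offset = 1 if one_based else 0
    return np.column_stack([pts[:, 1] - offset, pts[:, 0] - offset])


@dataclass
class ModelArchive:
    """Everything needed to trace: texture + smoothness models and config."""

    texture: TextureModel
    smoothness: sm.SmoothnessModel
    prior: PriorConfig
    window: int = 50
    convention: str = "strict"
    format_version: int = FORMAT_VERSION


def save_model(archive: ModelArchive, path: str | Path) -> None:
    meta = {
        "format_version": archive.format_version,
        "window": archive.window,
        "convention": archive.convention,
        "prior": {"mu": archive.prior.mu, "beta": archive.prior.beta},
    }
    buf = _stdio.BytesIO()
    joblib.dump(archive.texture, buf)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        zf.writestr("smoothness.txt", sm.save_text(archive.smoothness))
        zf.writestr("texture.joblib", buf.getvalue())


def load_model(path: str | Path) -> ModelArchive:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("format_version") != FORMAT_VERSION:
                raise ModelFormatError(
                    f"{path}: model format version {meta.get('format_version')} "
                    f"is not supported (expected {FORMAT_VERSION})")
            smodel = sm.load_text(zf.read("smoothness.txt").decode())
            texture = joblib.load(_stdio.BytesIO(zf.read("texture.joblib")))
    except (zipfile.BadZipFile, KeyError) as exc:
        raise ModelFormatError(f"{path}: corrupt model archive") from exc
    return ModelArchive(
        texture=texture,
        smoothness=smodel,
        prior=PriorConfig(**meta["prior"]),
        window=int(meta["window"]),
        convention=meta["convention"],
        format_version=int(meta["format_version"]),
    )
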