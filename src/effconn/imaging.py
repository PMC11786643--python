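"""Rendering of connectivity matrices as color raster images.

Matrices are put into the canonical 35-channel order (32 EEG then EXG1-3),
mapped through a fixed 256-entry blue-to-red lookup table and upscaled by
nearest neighbor so each matrix cell is a uniform pixel block. Rendering is
bit-deterministic: no plotting-library colormaps are involved.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image, PngImagePlugin

from .connectivity import ConnectivityMatrix
from .errors import ValidationError

#: canonical display order: 32 EEG channels then the three ECG leads
CANONICAL_35 = [
    "PO3", "O1", "C4", "F7", "FC5", "FC1", "Fp1", "CP1", "FC2", "Pz",
    "Fp2", "AF4", "Cz", "T8", "CP6", "AF3", "P3", "P7", "Oz", "F8",
    "CP5", "FC6", "F3", "C3", "Fz", "F4", "CP2", "P4", "P8", "PO4",
    "O2", "T7", "EXG1", "EXG2", "EXG3",
]


def _build_lut() -> np.ndarray:
    """Fixed blue->cyan->green->yellow->red lookup table, 256 x 3 uint8.

    Piecewise linear between five anchor colors; injective after uint8
    rounding (verified in the test suite), so block values can be recovered
    from rendered pixels by nearest-entry search.
    """
    anchors = np.array(
        [
            [0, 0, 143],     # dark blue
            [0, 112, 255],   # blue
            [0, 255, 112],   # green-cyan
            [255, 208, 0],   # yellow-orange
            [159, 0, 0],     # dark red
        ],
        dtype=float,
    )
    pos = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    t = np.linspace(0.0, 1.0, 256)
    lut = np.empty((256, 3))
    for c in range(3):
        lut[:, c] = np.interp(t, pos, anchors[:, c])
    return np.rint(lut).astype(np.uint8)


BLUE_RED_LUT = _build_lut()

_SCALINGS = ("unit-clamp", "one-minus-exp")


@dataclass
class ConnectivityImage:
    """An 8-bit RGB raster of a connectivity matrix plus its provenance."""

    pixels: np.ndarray  # (H, W, 3) uint8
    meta: dict = field(default_factory=dict)
    colormap: str = "blue-red"
    scaling: str = "unit-clamp"

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def order_channels(cm: ConnectivityMatrix, canonical: list[str] | None = None) -> ConnectivityMatrix:
    """Simultaneously permute rows and columns into the canonical label order."""
    canonical = canonical if canonical is not None else CANONICAL_35
    if sorted(cm.labels) != sorted(canonical):
        missing = sorted(set(canonical) - set(cm.labels))
        extra = sorted(set(cm.labels) - set(canonical))
        raise ValidationError(
            f"labels are not a permutation of the canonical list; "
            f"missing: {missing}, extra: {extra}"
        )
    idx = [cm.labels.index(lab) for lab in canonical]
    return replace(
        cm,
        values=cm.values[np.ix_(idx, idx)],
        labels=[cm.labels[i] for i in idx],
        kinds=[cm.kinds[i] for i in idx],
    )


def scale_values(values: np.ndarray, method: str) -> tuple[np.ndarray, str]:
    """Map raw connectivity values into [0, 1] with a fixed, image-independent map."""
    if method.upper() == "GC":
        return 1.0 - np.exp(-values), "one-minus-exp"
    return np.clip(values, 0.0, 1.0), "unit-clamp"


def render_image(cm: ConnectivityMatrix, size: int = 224,
                 colormap: str = "blue-red") -> ConnectivityImage:
    """Render an ordered matrix as a size x size RGB image (nearest-neighbor blocks)."""
    if colormap != "blue-red":
        raise ValidationError(f"unknown colormap {colormap!r}")
    values = np.asarray(cm.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("matrix contains NaN/Inf; cannot render")
    scaled, scaling = scale_values(values, cm.method)
    idx = np.rint(scaled * 255).astype(int)
    small = BLUE_RED_LUT[idx]  # (m, m, 3)
    m = values.shape[0]
    if size < m:
        raise ValidationError(f"size {size} smaller than matrix dimension {m}")
    # nearest-neighbor mapping: pixel p belongs to cell floor(p * m / size)
    cell = (np.arange(size) * m) // size
    pixels = small[np.ix_(cell, cell)]
    meta = {
        "method": cm.method,
        "band": cm.band,
        "emotion": cm.meta.get("emotion"),
        "subject_id": cm.meta.get("subject_id"),
        "orientation": cm.orientation,
    }
    return ConnectivityImage(pixels=pixels, meta=meta, colormap=colormap, scaling=scaling)


def invert_colormap(pixels: np.ndarray) -> np.ndarray:
    """Recover scaled values in [0,1] from rendered pixels by nearest-LUT search."""
    flat = pixels.reshape(-1, 3).astype(int)
    d2 = ((flat[:, None, :] - BLUE_RED_LUT[None].astype(int)) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)
    return (idx / 255.0).reshape(pixels.shape[:-1])


def save_image(img: ConnectivityImage, path: str | os.PathLike) -> None:
    """Write a PNG with metadata carried in text chunks."""
    info = PngImagePlugin.PngInfo()
    info.add_text("colormap", img.colormap)
    info.add_text("scaling", img.scaling)
    for key, value in img.meta.items():
        if value is not None:
            info.add_text(str(key), str(value))
    try:
        Image.fromarray(img.pixels, mode="RGB").save(path, format="PNG", pnginfo=info)
    except OSError as exc:
        raise IOError(f"cannot write image to {path}: {exc}") from exc


def load_image(path: str | os.PathLike) -> ConnectivityImage:
    try:
        with Image.open(path) as im:
            im.load()
            pixels = np.asarray(im.convert("RGB"))
            text = dict(im.text) if hasattr(im, "text") else {}
    except OSError as exc:
        raise IOError(f"cannot read image from {path}: {exc}") from exc
    colormap = text.pop("colormap", "blue-red")
    scaling = text.pop("scaling", "unit-clamp")
    return ConnectivityImage(pixels=pixels, meta=text, colormap=colormap, scaling=scaling)


def image_path(root: str | os.PathLike, cm: ConnectivityMatrix, window_index: int) -> str:
    """Directory layout <root>/<band>/<method>/<emotion>/<subject>_<window>.png."""
    emotion = cm.meta.get("emotion") or "unlabeled"
    subject = cm.meta.get("subject_id") or "anon"
    d = os.path.join(str(root), cm.band, cm.method.lower(), str(emotion))
    os.makedirs(d, exist_ok=True)
    return os.path.join(d, f"{subject}_{window_index:05d}.png")
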