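"""Reading serum-cuvette images and extracting ROI colour summaries."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

__all__ = [
    "RegionOfInterest",
    "ColourSummary",
    "read_image",
    "default_roi",
    "roi_mean",
    "weighted_intensity",
]

#: Rec.601 luma weights used for the weighted intensity channel.
REC601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class RegionOfInterest:
    """Rectangular ROI with 0-based, half-open extent [x0, x0+width)."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI width and height must be at least 1 pixel")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI offsets must be non-negative")

    def validate_within(self, shape) -> None:
        rows, cols = shape[0], shape[1]
        if self.x0 + self.width > cols or self.y0 + self.height > rows:
            raise ValueError(
                f"ROI (x0={self.x0}, y0={self.y0}, w={self.width}, h={self.height}) "
                f"exceeds image of {cols}x{rows} pixels"
            )


@dataclass(frozen=True)
class ColourSummary:
    r_mean: float
    g_mean: float
    b_mean: float
    intensity: float
    n_pixels: int

    def __post_init__(self) -> None:
        for name in ("r_mean", "g_mean", "b_mean", "intensity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be positive")


def read_image(path) -> np.ndarray:
    """Decode an image file to an (rows, cols, 3) uint8 array.

    Greyscale images are expanded to three equal channels; any alpha
    channel is discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as img:
            img = img.convert("RGB")
            arr = np.asarray(img, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise ValueError(f"not a decodable image: {path}") from exc
    return arr


def default_roi(image: np.ndarray) -> RegionOfInterest:
    """Centred square ROI covering 25% of the shorter image side."""
    rows, cols = image.shape[0], image.shape[1]
    side = max(1, round(0.25 * min(rows, cols)))
    return RegionOfInterest(
        x0=(cols - side) // 2, y0=(rows - side) // 2, width=side, height=side
    )


def roi_mean(image: np.ndarray, roi: RegionOfInterest | None = None) -> ColourSummary:
    """Per-channel arithmetic mean over the ROI, unrounded."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (rows, cols, 3) image array")
    if roi is None:
        roi = default_roi(image)
    roi.validate_within(image.shape)
    patch = image[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width, :]
    means = patch.reshape(-1, 3).mean(axis=0, dtype=float)
    return ColourSummary(
        r_mean=float(means[0]),
        g_mean=float(means[1]),
        b_mean=float(means[2]),
        intensity=float(weighted_intensity(*means)),
        n_pixels=roi.width * roi.height,
    )


def weighted_intensity(r_mean, g_mean, b_mean):
    """Rec.601-weighted mean of the channel means (accepts scalars or arrays)."""
    r = np.asarray(r_mean, dtype=float)
    g = np.asarray(g_mean, dtype=float)
    b = np.asarray(b_mean, dtype=float)
    for name, v in (("r_mean", r), ("g_mean", g), ("b_mean", b)):
        if np.any(v < 0.0) or np.any(v > 255.0):
            raise ValueError(f"{name} outside [0, 255]")
    wr, wg, wb = REC601_WEIGHTS
    out = wr * r + wg * g + wb * b
    return float(out) if out.ndim == 0 else out
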