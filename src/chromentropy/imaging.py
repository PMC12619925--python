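"""Photograph + polygon ROI -> gray-level histogram.

Pipeline: grayscale conversion, polygon rasterization to a pixel mask, and
masked histogram extraction. Coordinate convention throughout: 0-based pixel
indices, origin top-left, y increasing downward; polygon vertices live in
continuous pixel space; a pixel at column c, row r is inside a polygon iff
its center (c + 0.5, r + 0.5) is inside under the even-odd fill rule.

Only 8-bit images with 1 or 3 channels are accepted. An alpha channel is
stripped on load; transparency does not exclude pixels from masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np
from PIL import Image

from .core import EntropyResult, GrayHistogram, N_LEVELS, normalize_histogram, shannon_entropy
from .errors import EmptyROIError, InvalidPolygonError, UnsupportedImageError

__all__ = [
    "RasterImage",
    "PolygonROI",
    "PixelMask",
    "GRAYSCALE_METHODS",
    "load_image",
    "to_grayscale",
    "rasterize_polygon",
    "roi_histogram",
    "compute_roi_entropy",
    "save_mask_png",
]

GRAYSCALE_METHODS = ("unweighted_mean", "luma_bt601")


@dataclass(frozen=True)
class RasterImage:
    """8-bit raster image, row-major, origin top-left.

    ``pixels`` has shape (height, width) for grayscale or
    (height, width, 3) for RGB, dtype uint8.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            raise UnsupportedImageError(
                f"only 8-bit images are supported, got dtype {px.dtype}"
            )
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        if not (px.ndim == 2 or (px.ndim == 3 and px.shape[2] == 3)):
            raise UnsupportedImageError(
                f"image must have 1 or 3 channels, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise UnsupportedImageError("image must have positive dimensions")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else int(self.pixels.shape[2])

    def save(self, path: Union[str, Path]) -> None:
        Image.fromarray(self.pixels).save(str(path))


@dataclass(frozen=True)
class PolygonROI:
    """Ordered polygon vertices (x, y) in continuous pixel space."""

    vertices: Tuple[Tuple[float, float], ...]
    name: str = ""

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise InvalidPolygonError(
                f"polygon needs at least 3 vertices, got {len(verts)}"
            )
        if _collinear(verts):
            raise InvalidPolygonError("polygon has zero area (collinear vertices)")
        object.__setattr__(self, "vertices", verts)

    @property
    def area(self) -> float:
        """Absolute shoelace area in square pixels."""
        return abs(_signed_area(self.vertices))

    def translated(self, dx: float, dy: float) -> "PolygonROI":
        return PolygonROI(
            tuple((x + dx, y + dy) for x, y in self.vertices), name=self.name
        )


def _collinear(verts: Sequence[Tuple[float, float]]) -> bool:
    """All vertices on one line? (Signed area alone misses bow-ties, whose
    lobes cancel to zero while still enclosing pixels under even-odd.)"""
    x0, y0 = verts[0]
    return all(
        (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0) == 0.0
        for (x1, y1), (x2, y2) in zip(verts[1:], verts[2:])
    )


def _signed_area(verts: Sequence[Tuple[float, float]]) -> float:
    xs = np.array([v[0] for v in verts])
    ys = np.array([v[1] for v in verts])
    return 0.5 * float(np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys))


@dataclass(frozen=True)
class PixelMask:
    """Boolean inside-flags, same shape as the target image."""

    inside: np.ndarray

    def __post_init__(self) -> None:
        inside = np.asarray(self.inside, dtype=bool)
        if inside.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "inside", inside)

    @property
    def height(self) -> int:
        return int(self.inside.shape[0])

    @property
    def width(self) -> int:
        return int(self.inside.shape[1])

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())


def load_image(path: Union[str, Path]) -> RasterImage:
    """Read a PNG/TIFF/JPEG photograph as an 8-bit RasterImage.

    Alpha channels are stripped; palette images are expanded; 16-bit or
    float images are rejected rather than rescaled.
    """
    with Image.open(str(path)) as im:
        mode = im.mode
        if mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            raise UnsupportedImageError(
                f"{path}: {mode}-mode (non-8-bit) images are not supported"
            )
        if mode == "P":
            im = im.convert("RGB")
        elif mode == "RGBA":
            im = im.convert("RGB")
        elif mode == "LA":
            im = im.convert("L")
        elif mode not in ("L", "RGB"):
            im = im.convert("RGB")
        arr = np.asarray(im, dtype=np.uint8)
    return RasterImage(arr)


def to_grayscale(image: RasterImage, method: str = "unweighted_mean") -> RasterImage:
    """Collapse RGB to one 8-bit gray channel.

    ``unweighted_mean`` maps each pixel to round((r+g+b)/3); ``luma_bt601``
    to round(0.299 r + 0.587 g + 0.114 b). Rounding is half away from zero
    (``floor(x + 0.5)`` on non-negative values, as ImageJ does). A 1-channel
    input is returned unchanged regardless of method.
    """
    if method not in GRAYSCALE_METHODS:
        raise ValueError(f"unknown grayscale method {method!r}; choose from {GRAYSCALE_METHODS}")
    if image.channels == 1:
        return image
    rgb = image.pixels.astype(np.float64)
    if method == "unweighted_mean":
        gray = rgb.sum(axis=2) / 3.0
    else:
        gray = rgb @ np.array([0.299, 0.587, 0.114])
    gray = np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)
    return RasterImage(gray)


def rasterize_polygon(roi: PolygonROI, width: int, height: int) -> PixelMask:
    """Discretize a polygon to the pixel grid.

    A pixel (c, r) is inside iff its center (c + 0.5, r + 0.5) lies inside
    the polygon under the even-odd rule, computed by counting crossings of a
    leftward horizontal ray with the polygon's edges. Vertices may fall
    outside the image; the mask is clipped to the frame.
    """
    if width < 1 or height < 1:
        raise ValueError("mask dimensions must be positive")
    xs = np.arange(width, dtype=np.float64) + 0.5
    ys = np.arange(height, dtype=np.float64) + 0.5
    inside = np.zeros((height, width), dtype=bool)
    verts = roi.vertices
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        # rows whose center ordinate is straddled by this edge (half-open
        # rule so a vertex shared by two edges is counted once)
        straddle = (y1 > ys) != (y2 > ys)
        if not straddle.any():
            continue
        yr = ys[straddle]
        x_cross = x1 + (yr - y1) * (x2 - x1) / (y2 - y1)
        inside[straddle] ^= xs[None, :] < x_cross[:, None]
    return PixelMask(inside)


def roi_histogram(gray: RasterImage, mask: PixelMask) -> GrayHistogram:
    """Tally gray values of the pixels under the mask into 256 bins."""
    if gray.channels != 1:
        raise UnsupportedImageError("roi_histogram needs a 1-channel image; convert first")
    if (gray.height, gray.width) != (mask.height, mask.width):
        raise ValueError(
            f"image {gray.height}x{gray.width} and mask {mask.height}x{mask.width} "
            "dimensions differ"
        )
    if mask.n_inside < 1:
        raise EmptyROIError("mask selects no pixels (polygon misses the image?)")
    values = gray.pixels[mask.inside]
    counts = np.bincount(values, minlength=N_LEVELS)
    return GrayHistogram(counts)


def compute_roi_entropy(
    image: RasterImage,
    roi: PolygonROI,
    method: str = "unweighted_mean",
    label: str = "",
) -> EntropyResult:
    """End-to-end per-ROI entropy: grayscale -> mask -> histogram -> H.

    The returned result records the grayscale method and bin count so that
    relative-entropy pairing can verify both ROIs were processed alike.
    """
    gray = to_grayscale(image, method)
    mask = rasterize_polygon(roi, image.width, image.height)
    hist = roi_histogram(gray, mask)
    h = shannon_entropy(normalize_histogram(hist))
    return EntropyResult(
        label=label or roi.name,
        roi_pixels=mask.n_inside,
        h_bits=h,
        grayscale_method=method,
        bins=N_LEVELS,
    )


def save_mask_png(mask: PixelMask, path: Union[str, Path]) -> None:
    """Write a 0/255 mask image for visual QC of the rasterized ROI."""
    arr = np.where(mask.inside, 255, 0).astype(np.uint8)
    Image.fromarray(arr).save(str(path))
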