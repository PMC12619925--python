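"""Phantom images with analytically known histograms and entropies.

The study conditions this package targets — a photographed lesion plus
perilesional control skin — are emulated by two phantom families:

* **Exact-histogram phantoms**: the full-frame histogram equals a prescribed
  256-bin count vector *exactly* (pixel values are laid out
  deterministically, then spatially permuted with a seeded generator), so
  the analytic entropy of the spec is recovered bit-for-bit.
* **Two-region lesion phantoms**: pixels inside a lesion polygon are i.i.d.
  draws from a lesion gray-level distribution, the rest from a background
  distribution, mimicking the lesion/perilesional-control pairing. Measured
  entropies then converge to the analytic values as ROI pixel counts grow
  (plug-in estimator, negatively biased at finite n).

Pixels are i.i.d.: entropy of a histogram is spatially blind, so no texture
or correlation model is needed to exercise the pipeline. All generation is
a pure function of the spec including its seed (numpy PCG64 via
``default_rng``), so fixtures are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Tuple

import numpy as np

from .core import (
    GrayHistogram,
    N_LEVELS,
    ProbabilityDistribution,
    shannon_entropy,
)
from .errors import ChromentropyError
from .imaging import PixelMask, PolygonROI, RasterImage, rasterize_polygon

__all__ = [
    "PhantomSpec",
    "exact_histogram_phantom",
    "lesion_phantom",
    "empirical_vs_analytic_entropy",
    "uniform_levels_distribution",
    "single_level_distribution",
]


def uniform_levels_distribution(n_levels: int, offset: int = 0) -> ProbabilityDistribution:
    """Uniform distribution over ``n_levels`` consecutive gray values starting
    at ``offset`` (analytic entropy log2(n_levels) bits), embedded in 256 bins."""
    if not (1 <= n_levels <= N_LEVELS) or not (0 <= offset <= N_LEVELS - n_levels):
        raise ValueError("levels must fit inside 0..255")
    p = np.zeros(N_LEVELS)
    p[offset : offset + n_levels] = 1.0 / n_levels
    return ProbabilityDistribution(p)


def single_level_distribution(level: int) -> ProbabilityDistribution:
    """Point mass at one gray value (analytic entropy 0 bits)."""
    if not (0 <= level < N_LEVELS):
        raise ValueError("level must lie in 0..255")
    p = np.zeros(N_LEVELS)
    p[level] = 1.0
    return ProbabilityDistribution(p)


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a phantom image.

    Exactly one family must be configured: set ``target_counts`` for an
    exact-histogram phantom, or ``background_dist`` + ``lesion_dist`` +
    ``lesion_polygon`` for a two-region lesion phantom. ``channels=3``
    replicates the gray values into RGB so the grayscale-conversion path is
    exercised too.
    """

    width: int
    height: int
    seed: int
    target_counts: Optional[np.ndarray] = None
    background_dist: Optional[ProbabilityDistribution] = None
    lesion_dist: Optional[ProbabilityDistribution] = None
    lesion_polygon: Optional[PolygonROI] = None
    channels: int = 1

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("phantom dimensions must be positive")
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        exact = self.target_counts is not None
        two_region = all(
            f is not None
            for f in (self.background_dist, self.lesion_dist, self.lesion_polygon)
        )
        if exact == two_region:
            raise ValueError(
                "set either target_counts (exact phantom) or background_dist + "
                "lesion_dist + lesion_polygon (two-region phantom), not both"
            )
        if exact:
            counts = np.asarray(self.target_counts, dtype=np.int64)
            if counts.shape != (N_LEVELS,) or np.any(counts < 0):
                raise ValueError("target_counts must be 256 non-negative integers")
            if int(counts.sum()) != self.width * self.height:
                raise ValueError(
                    f"target_counts sum to {int(counts.sum())}, but the frame has "
                    f"{self.width * self.height} pixels"
                )
            object.__setattr__(self, "target_counts", counts)
        else:
            for d in (self.background_dist, self.lesion_dist):
                if d.n_levels != N_LEVELS:
                    raise ValueError("phantom distributions must cover all 256 levels")

    @property
    def kind(self) -> str:
        return "exact" if self.target_counts is not None else "lesion"


def _finish(gray: np.ndarray, channels: int) -> RasterImage:
    if channels == 3:
        gray = np.repeat(gray[:, :, None], 3, axis=2)
    return RasterImage(gray)


def exact_histogram_phantom(spec: PhantomSpec) -> RasterImage:
    """Emit an image whose full-frame histogram equals ``spec.target_counts``.

    Each gray value i appears exactly ``target_counts[i]`` times; the seeded
    generator only permutes pixel positions, so the histogram equality is by
    construction, not sampling. Same spec (including seed) -> identical image.
    """
    if spec.kind != "exact":
        raise ValueError("spec is not an exact-histogram phantom spec")
    values = np.repeat(np.arange(N_LEVELS, dtype=np.uint8), spec.target_counts)
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(values)
    return _finish(values.reshape(spec.height, spec.width), spec.channels)


def lesion_phantom(
    spec: PhantomSpec,
) -> Tuple[RasterImage, PolygonROI, PolygonROI]:
    """Two-region phantom: lesion pixels vs background pixels, plus ROIs.

    Returns (image, lesion_roi, control_roi). The control ROI is the largest
    rectangular strip of pure background flanking the lesion's bounding box
    (one pixel of clearance on each side), standing in for perilesional
    skin. Raises if the lesion leaves no room for a control region.
    """
    if spec.kind != "lesion":
        raise ValueError("spec is not a two-region lesion phantom spec")
    w, h = spec.width, spec.height
    mask = rasterize_polygon(spec.lesion_polygon, w, h)
    if mask.n_inside == 0:
        raise ChromentropyError("lesion polygon covers no pixels of the frame")

    rng = np.random.default_rng(spec.seed)
    gray = rng.choice(N_LEVELS, size=(h, w), p=spec.background_dist.p).astype(np.uint8)
    gray[mask.inside] = rng.choice(
        N_LEVELS, size=mask.n_inside, p=spec.lesion_dist.p
    ).astype(np.uint8)

    control = _control_rectangle(mask)
    if control is None:
        raise ChromentropyError(
            "lesion polygon fills the frame; no room for a disjoint control ROI"
        )
    return _finish(gray, spec.channels), spec.lesion_polygon, control


def _control_rectangle(mask: PixelMask) -> Optional[PolygonROI]:
    """Largest margin strip beside the lesion bounding box, or None."""
    rows = np.flatnonzero(mask.inside.any(axis=1))
    cols = np.flatnonzero(mask.inside.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1])
    c0, c1 = int(cols[0]), int(cols[-1])
    h, w = mask.inside.shape
    # candidate strips: (x_lo, y_lo, x_hi, y_hi) in continuous coordinates,
    # each one pixel clear of the bounding box
    candidates = [
        (0.0, 0.0, float(c0 - 1), float(h)),        # left of lesion
        (float(c1 + 2), 0.0, float(w), float(h)),   # right
        (0.0, 0.0, float(w), float(r0 - 1)),        # above
        (0.0, float(r1 + 2), float(w), float(h)),   # below
    ]
    best = None
    best_area = 0.0
    for x_lo, y_lo, x_hi, y_hi in candidates:
        area = max(0.0, x_hi - x_lo) * max(0.0, y_hi - y_lo)
        if area > best_area:
            best_area = area
            best = (x_lo, y_lo, x_hi, y_hi)
    if best is None or best_area < 1.0:
        return None
    x_lo, y_lo, x_hi, y_hi = best
    return PolygonROI(
        ((x_lo, y_lo), (x_hi, y_lo), (x_hi, y_hi), (x_lo, y_hi)),
        name="control",
    )


class EmpiricalEntropyReport(NamedTuple):
    h_measured: float
    h_analytic: float
    abs_error: float


def empirical_vs_analytic_entropy(
    dist: ProbabilityDistribution, n_pixels: int, seed: int
) -> EmpiricalEntropyReport:
    """Plug-in entropy of ``n_pixels`` seeded i.i.d. draws vs the analytic H.

    Quantifies the finite-sample (negative) bias of the empirical estimator;
    the absolute error shrinks to 0 as n grows.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    h_analytic = shannon_entropy(dist)
    rng = np.random.default_rng(seed)
    draws = rng.choice(dist.n_levels, size=n_pixels, p=dist.p)
    freqs = np.bincount(draws, minlength=dist.n_levels) / float(n_pixels)
    h_measured = shannon_entropy(ProbabilityDistribution(freqs))
    return EmpiricalEntropyReport(h_measured, h_analytic, abs(h_measured - h_analytic))
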