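"""Shannon entropy of gray-level histograms and lesion-vs-control relative entropy.

The quantity of interest is the Shannon entropy of the gray-level
distribution inside a region of interest (ROI),

    H = -sum_i p_i * log2(p_i)        [bits],

where ``p_i`` is the probability of intensity level ``i`` (0..255) among the
ROI's pixels. For an 8-bit image H lies in [0, 8]: 0 for a perfectly
homogeneous region, 8 for a region uniform over all 256 levels. H measures
histogram heterogeneity — a proxy for color variegation once the photograph
is reduced to grayscale.

Because baseline skin heterogeneity (age, phototype, photodamage) shifts H,
lesions are scored against a perilesional-skin internal control from the
same photograph:

    dH = H_lesion - H_control         [bits, may be negative].

dH is a plain difference of entropies, not a Kullback-Leibler divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import EmptyROIError, ProvenanceMismatchError, UnnormalizedDistributionError

__all__ = [
    "GrayHistogram",
    "ProbabilityDistribution",
    "EntropyResult",
    "RelativeEntropyResult",
    "normalize_histogram",
    "shannon_entropy",
    "relative_entropy",
    "max_entropy",
    "N_LEVELS",
    "SUM_TOLERANCE",
]

#: Number of gray levels in an 8-bit image.
N_LEVELS = 256

#: Absolute tolerance on |sum(p) - 1| before a distribution is rejected as
#: unnormalized. Beyond this the input is an error, never silently rescaled.
SUM_TOLERANCE = 1e-9


@dataclass(frozen=True)
class GrayHistogram:
    """Pixel counts per intensity level for one ROI.

    Parameters
    ----------
    counts
        Sequence of exactly 256 non-negative integers; ``counts[i]`` is the
        number of ROI pixels with gray value ``i``.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (N_LEVELS,):
            raise ValueError(
                f"histogram must have exactly {N_LEVELS} bins, got shape {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError("histogram counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ProbabilityDistribution:
    """Normalized bin probabilities ``p_i``.

    Length is 256 for gray-level distributions but any length >= 1 is
    accepted so that coarsened or truncated distributions can be handled.
    Construction validates ``p_i in [0, 1]`` and ``|sum(p) - 1| <= 1e-9``.
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.ndim != 1 or p.size < 1:
            raise UnnormalizedDistributionError(
                "probability vector must be 1-D with at least one bin"
            )
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise UnnormalizedDistributionError("probabilities must lie in [0, 1]")
        total = float(p.sum())
        if abs(total - 1.0) > SUM_TOLERANCE:
            raise UnnormalizedDistributionError(
                f"probabilities sum to {total!r}, not 1 within {SUM_TOLERANCE}"
            )
        object.__setattr__(self, "p", p)

    @property
    def n_levels(self) -> int:
        return int(self.p.size)


@dataclass(frozen=True)
class EntropyResult:
    """One ROI's entropy measurement: label, pixel count, H in bits.

    ``grayscale_method`` and ``bins`` record the processing convention the
    value was computed under; relative entropy refuses to compare results
    computed under different conventions.
    """

    label: str
    roi_pixels: int
    h_bits: float
    grayscale_method: Union[str, None] = None
    bins: int = N_LEVELS

    def __post_init__(self) -> None:
        if self.roi_pixels < 1:
            raise ValueError("roi_pixels must be a positive integer")
        bound = max_entropy(self.bins)
        if not (-1e-12 <= self.h_bits <= bound + 1e-12):
            raise ValueError(
                f"h_bits={self.h_bits} outside [0, {bound}] for {self.bins} bins"
            )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "roi_pixels": self.roi_pixels,
            "h_bits": self.h_bits,
            "grayscale_method": self.grayscale_method,
            "bins": self.bins,
        }


@dataclass(frozen=True)
class RelativeEntropyResult:
    """Lesion-vs-control pairing and dH = H_lesion - H_control in bits."""

    lesion_label: str
    control_label: str
    delta_h_bits: float

    def to_dict(self) -> dict:
        return {
            "lesion_label": self.lesion_label,
            "control_label": self.control_label,
            "delta_h_bits": self.delta_h_bits,
        }


def normalize_histogram(hist: GrayHistogram) -> ProbabilityDistribution:
    """Convert pixel counts to normalized probabilities ``p_i = n_i / N``.

    Raises
    ------
    EmptyROIError
        If the histogram total is zero (no pixels to normalize).
    """
    total = hist.total_pixels
    if total < 1:
        raise EmptyROIError("histogram has zero total pixels: empty ROI")
    return ProbabilityDistribution(hist.counts / float(total))


def shannon_entropy(dist: Union[ProbabilityDistribution, Sequence[float]]) -> float:
    """Shannon entropy ``H = -sum p_i log2 p_i`` in bits.

    Terms with ``p_i = 0`` contribute exactly 0 (the ``0·log2(0) := 0``
    convention). Accepts a :class:`ProbabilityDistribution` or any sequence,
    which is validated on the way in; an unnormalized input raises
    :class:`~chromentropy.errors.UnnormalizedDistributionError`.
    """
    if not isinstance(dist, ProbabilityDistribution):
        dist = ProbabilityDistribution(np.asarray(dist, dtype=np.float64))
    p = dist.p[dist.p > 0.0]
    # + 0.0 normalizes the -0.0 produced by negating an all-zero sum
    return float(-np.sum(p * np.log2(p))) + 0.0


def relative_entropy(lesion: EntropyResult, control: EntropyResult) -> RelativeEntropyResult:
    """dH = lesion H minus control H, carrying both labels.

    Only meaningful within one processing convention, so the two results
    must share grayscale method (when recorded) and bin count.
    """
    if lesion.bins != control.bins:
        raise ProvenanceMismatchError(
            f"bin counts differ: {lesion.bins} vs {control.bins}"
        )
    if (
        lesion.grayscale_method is not None
        and control.grayscale_method is not None
        and lesion.grayscale_method != control.grayscale_method
    ):
        raise ProvenanceMismatchError(
            "grayscale methods differ: "
            f"{lesion.grayscale_method!r} vs {control.grayscale_method!r}"
        )
    return RelativeEntropyResult(
        lesion_label=lesion.label,
        control_label=control.label,
        delta_h_bits=lesion.h_bits - control.h_bits,
    )


def max_entropy(n_levels: int) -> float:
    """Maximum attainable entropy, ``log2(n_levels)`` bits.

    Attained only by the uniform distribution over all ``n_levels`` bins.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    return math.log2(n_levels)
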