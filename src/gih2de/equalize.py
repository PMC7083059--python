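"""Gradient-interval histogram (GIH) and GIH equalization (GIHE).

In a gel image the background varies slowly while the edges of protein
spots vary quickly.  The gradient interval histogram exploits this: each
pixel looks at the minimum and maximum gray value in its 3x3
neighborhood and increments *every* histogram bin between them.  Pixels
in flat regions contribute a single count (the ordinary histogram);
pixels on steep spot edges smear their count across the whole local
gray-value interval.  Equalizing against this histogram therefore
stretches contrast exactly at the gray levels occupied by spot edges --
in particular the faint edges of weak, low-abundance spots -- while the
over-represented background peak no longer dominates the mapping the way
it does in plain histogram equalization.

The derivative of the equalization map at level ``k`` is
``(L-1) * p(k)`` where ``p`` is the GIH-derived probability density, so
contrast at level ``k`` is stretched exactly when ``p(k) > 1/(L-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi

from .image import GrayImage

__all__ = [
    "GradientIntervalHistogram",
    "Distribution",
    "GrayLevelMapping",
    "compute_gih",
    "compute_distribution",
    "equalization_mapping",
    "apply_mapping",
    "gihe",
    "GiheResult",
    "mapping_slope",
]


@dataclass(frozen=True)
class GradientIntervalHistogram:
    """Per-level counts accumulated over per-pixel neighborhood intervals.

    ``counts[k]`` is the number of pixels whose 3x3-window gray-value
    interval ``[k_min, k_max]`` contains ``k``.  The total count is
    ``sum over pixels of (k_max - k_min + 1)`` and is therefore at least
    ``H * W``.
    """

    counts: np.ndarray
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def levels(self) -> int:
        return self.counts.shape[0]

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Distribution:
    """A discrete gray-level PDF with its cumulative distribution."""

    pdf: np.ndarray
    cdf: np.ndarray

    def __post_init__(self) -> None:
        pdf = np.asarray(self.pdf, dtype=np.float64)
        cdf = np.asarray(self.cdf, dtype=np.float64)
        if pdf.shape != cdf.shape or pdf.ndim != 1:
            raise ValueError("pdf and cdf must be 1-D vectors of equal length")
        if (pdf < 0).any():
            raise ValueError("pdf must be non-negative")
        if abs(pdf.sum() - 1.0) > 1e-9:
            raise ValueError(f"pdf must sum to 1, got {pdf.sum()!r}")
        if (np.diff(cdf) < -1e-12).any():
            raise ValueError("cdf must be non-decreasing")
        if abs(cdf[-1] - 1.0) > 1e-9:
            raise ValueError(f"cdf must end at 1, got {cdf[-1]!r}")
        object.__setattr__(self, "pdf", pdf)
        object.__setattr__(self, "cdf", cdf)

    @property
    def levels(self) -> int:
        return self.pdf.shape[0]

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "Distribution":
        counts = np.asarray(counts, dtype=np.float64)
        total = counts.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero histogram")
        pdf = counts / total
        return cls(pdf, np.cumsum(pdf))


@dataclass(frozen=True)
class GrayLevelMapping:
    """A monotone lookup table sending old gray levels to new ones."""

    table: np.ndarray

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=np.int64)
        if table.ndim != 1:
            raise ValueError("mapping table must be 1-D")
        L = table.shape[0]
        if table.min() < 0 or table.max() > L - 1:
            raise ValueError(f"table entries must lie in [0, {L - 1}]")
        if (np.diff(table) < 0).any():
            raise ValueError("mapping table must be monotone non-decreasing")
        object.__setattr__(self, "table", table)

    def __len__(self) -> int:
        return self.table.shape[0]

    @classmethod
    def identity(cls, levels: int) -> "GrayLevelMapping":
        return cls(np.arange(levels))


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # deterministic half-up rounding; np.round would round halves to even
    return np.floor(x + 0.5).astype(np.int64)


def compute_gih(
    img: GrayImage, *, include_center: bool = True
) -> GradientIntervalHistogram:
    """Build the gradient interval histogram of an image.

    For every pixel, ``k_min`` / ``k_max`` are the extrema of the gray
    values over its 3x3 window (clipped at image borders); all bins in
    ``[k_min, k_max]`` receive one count.

    Parameters
    ----------
    img:
        Input image.
    include_center:
        If True (default) the window is the full 3x3 block including the
        pixel itself, so ``k_min <= v <= k_max`` always holds and the GIH
        is a superset of the ordinary histogram.  If False only the 8
        surrounding neighbors are scanned.
    """
    a = img.pixels.astype(np.int64)
    L = img.levels
    if include_center:
        # replicate-padding is equivalent to clipping the window: the
        # padded value duplicates an in-window pixel, so it never changes
        # the min or max
        kmin = ndi.minimum_filter(a, size=3, mode="nearest")
        kmax = ndi.maximum_filter(a, size=3, mode="nearest")
    else:
        fp = np.ones((3, 3), dtype=bool)
        fp[1, 1] = False
        # out-of-image positions get a sentinel that can never win
        kmin = ndi.minimum_filter(a, footprint=fp, mode="constant", cval=L)
        kmax = ndi.maximum_filter(a, footprint=fp, mode="constant", cval=-1)
        empty = kmax < kmin  # 1x1 image: no neighbors at all
        kmin[empty] = a[empty]
        kmax[empty] = a[empty]

    # accumulate intervals [kmin, kmax] with a difference array
    start = np.bincount(kmin.ravel(), minlength=L + 1)[: L + 1]
    stop = np.bincount(kmax.ravel() + 1, minlength=L + 1)[: L + 1]
    counts = np.cumsum(start - stop)[:L]
    return GradientIntervalHistogram(counts, img.shape)


def compute_distribution(gih: GradientIntervalHistogram) -> Distribution:
    """Normalize a histogram into a PDF and its CDF."""
    return Distribution.from_counts(gih.counts)


def equalization_mapping(dist: Distribution) -> GrayLevelMapping:
    """Equalization lookup table ``k -> round((L-1) * cdf(k))``."""
    L = dist.levels
    table = np.clip(_round_half_up((L - 1) * dist.cdf), 0, L - 1)
    return GrayLevelMapping(table)


def apply_mapping(img: GrayImage, mapping: GrayLevelMapping) -> GrayImage:
    """Apply a gray-level lookup table pixelwise."""
    if len(mapping) != img.levels:
        raise ValueError(
            f"mapping has {len(mapping)} entries but image declares "
            f"{img.levels} levels"
        )
    return GrayImage(mapping.table[img.pixels], img.levels)


class GiheResult(NamedTuple):
    image: GrayImage
    distribution: Distribution
    mapping: GrayLevelMapping


def gihe(img: GrayImage, *, include_center: bool = True) -> GiheResult:
    """GIH equalization: equalize an image against its gradient interval
    histogram, returning the result together with the intermediate
    distribution and lookup table."""
    dist = compute_distribution(compute_gih(img, include_center=include_center))
    mapping = equalization_mapping(dist)
    return GiheResult(apply_mapping(img, mapping), dist, mapping)


def mapping_slope(dist: Distribution, k: int) -> float:
    """Slope of the equalization map at level ``k``: ``(L-1) * pdf[k]``.

    Contrast at level ``k`` is stretched iff the slope exceeds 1,
    i.e. iff ``pdf[k] > 1 / (L-1)``.
    """
    if not 1 <= k <= dist.levels - 1:
        raise ValueError(f"k must be in [1, {dist.levels - 1}], got {k}")
    return float((dist.levels - 1) * dist.pdf[k])
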