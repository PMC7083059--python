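"""Spot-level quantification metrics for evaluating brightness correction.

The quantities implemented here are the standard area-based measures of
2DE proteomics:

* *gray value difference* ``d(k)``: mean gray value of a spot's center
  pixels minus the mean of its local background -- negative for a dark
  spot on a bright gel, and the quantity that h-dome based detection
  ultimately depends on;
* *spot volume*: the sum of pixel intensities over the spot region,
  identically ``area x mean_intensity``;
* *mean/variance normalization*: ``G' = M0 + (G - M) * sqrt(V0 / V)``
  with ``M0 = V0 = 127``, bringing two images to a common intensity
  scale before comparing spot quantities (population statistics over all
  pixels);
* *CPS quantification error* ``D_k``: the signed relative difference of
  the mean intensities of a corresponding protein-spot pair, in percent
  of their average -- and its absolute mean over all pairs, the headline
  figure of merit for brightness correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .equalize import Distribution
from .image import GrayImage

__all__ = [
    "SpotRecord",
    "CpsPair",
    "gray_value_difference",
    "spot_volume",
    "normalize_image",
    "quantification_error",
    "average_cps_error",
    "enhancement_heatmap",
]


def _as_array(img: GrayImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, GrayImage) else np.asarray(img)


def _coords(pixels: np.ndarray | Sequence) -> np.ndarray:
    arr = np.asarray(pixels, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pixel coordinates must be an (N, 2) array of (row, col)")
    return arr


def _coord_set(arr: np.ndarray) -> set[tuple[int, int]]:
    return {(int(r), int(c)) for r, c in arr}


@dataclass(frozen=True)
class SpotRecord:
    """One detected protein spot.

    ``center_pixels`` is the small cap of pixels at the spot's intensity
    extremum, ``region_pixels`` the full segmented spot area, and
    ``background_pixels`` a ring of local-background pixels around the
    contour.  ``mean_intensity`` and ``volume`` are measured on a
    specific image via :meth:`measure`; the identity
    ``volume == area * mean_intensity`` holds by construction.
    """

    spot_id: int
    center_pixels: np.ndarray
    region_pixels: np.ndarray
    background_pixels: np.ndarray
    mean_intensity: float
    volume: float
    is_weak: bool | None = None

    def __post_init__(self) -> None:
        center = _coords(self.center_pixels)
        region = _coords(self.region_pixels)
        background = _coords(self.background_pixels)
        region_set = _coord_set(region)
        if not _coord_set(center) <= region_set:
            raise ValueError("center pixels must be a subset of the region")
        if _coord_set(background) & region_set:
            raise ValueError("background pixels must be disjoint from the region")
        if region.shape[0] > 0:
            expected = self.area * self.mean_intensity
            if abs(self.volume - expected) > 1e-9 * max(1.0, abs(expected)):
                raise ValueError("volume must equal area * mean_intensity")
        object.__setattr__(self, "center_pixels", center)
        object.__setattr__(self, "region_pixels", region)
        object.__setattr__(self, "background_pixels", background)

    @property
    def area(self) -> int:
        return self.region_pixels.shape[0]

    @classmethod
    def measure(
        cls,
        img: GrayImage | np.ndarray,
        spot_id: int,
        center_pixels,
        region_pixels,
        background_pixels,
        is_weak: bool | None = None,
    ) -> "SpotRecord":
        """Build a record with intensity statistics taken from ``img``."""
        region = _coords(region_pixels)
        if region.shape[0] == 0:
            raise ValueError("spot region must be non-empty")
        a = _as_array(img)
        vals = a[region[:, 0], region[:, 1]].astype(np.float64)
        mean = float(vals.mean())
        return cls(
            spot_id=spot_id,
            center_pixels=center_pixels,
            region_pixels=region,
            background_pixels=background_pixels,
            mean_intensity=mean,
            volume=float(region.shape[0]) * mean,
            is_weak=is_weak,
        )


@dataclass(frozen=True)
class CpsPair:
    """A corresponding protein-spot pair with its quantification error.

    ``d_percent`` is signed: it is zero iff the two mean intensities are
    equal and changes sign when the images are swapped.
    """

    spot_id: int
    q_a: float
    q_b: float
    d_percent: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "d_percent", quantification_error(self.q_a, self.q_b)
        )


def gray_value_difference(img: GrayImage | np.ndarray, spot: SpotRecord) -> float:
    """Mean gray value over the spot center minus the local background mean."""
    a = _as_array(img)
    center = spot.center_pixels
    background = spot.background_pixels
    if center.shape[0] == 0 or background.shape[0] == 0:
        raise ValueError("spot must have non-empty center and background pixels")
    mc = a[center[:, 0], center[:, 1]].astype(np.float64).mean()
    mb = a[background[:, 0], background[:, 1]].astype(np.float64).mean()
    return float(mc - mb)


def spot_volume(
    img: GrayImage | np.ndarray, spot: SpotRecord
) -> tuple[int, float, float]:
    """``(area, mean_intensity, volume)`` of a spot measured on ``img``."""
    region = spot.region_pixels
    if region.shape[0] == 0:
        raise ValueError("spot region must be non-empty")
    a = _as_array(img)
    vals = a[region[:, 0], region[:, 1]].astype(np.float64)
    mean = float(vals.mean())
    return region.shape[0], mean, float(region.shape[0] * mean)


def normalize_image(
    img: GrayImage | np.ndarray, M0: float = 127.0, V0: float = 127.0
) -> np.ndarray:
    """Normalize to mean ``M0`` and variance ``V0`` (population statistics).

    Output is real-valued and is intentionally not re-quantized: spot
    quantities are compared on the continuous scale.  A constant image
    has undefined normalization and raises.
    """
    a = _as_array(img).astype(np.float64)
    M = a.mean()
    V = a.var()
    if V <= 0:
        raise ValueError("cannot normalize a constant image (zero variance)")
    return M0 + (a - M) * np.sqrt(V0 / V)


def quantification_error(q_a: float, q_b: float) -> float:
    """Signed relative difference of a spot pair, percent of the pair mean."""
    if q_a + q_b <= 0:
        raise ValueError("mean intensities must have a positive sum")
    return float((q_a - q_b) / ((q_a + q_b) / 2.0) * 100.0)


def average_cps_error(pairs: Iterable[CpsPair]) -> float:
    """Mean of ``|D_k|`` over all pairs (signed values live on each pair)."""
    ds = [abs(p.d_percent) for p in pairs]
    if not ds:
        raise ValueError("need at least one CPS pair")
    return float(np.mean(ds))


def enhancement_heatmap(
    img: GrayImage, dist: Distribution
) -> np.ndarray:
    """Per-pixel probability density ``pdf[img(x, y)]``.

    Because the equalization slope at level ``k`` is ``(L-1) * pdf[k]``,
    this image shows where in the gel the correction stretches contrast:
    bright values sit on spot edges when the distribution comes from the
    GIH.
    """
    if dist.levels != img.levels:
        raise ValueError("distribution and image must share a level count")
    return dist.pdf[img.pixels]
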