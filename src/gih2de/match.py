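"""GIH matching (GIHM): remove overall brightness shifts between gels.

Two gels of the same sample should show the same intensity
distribution; in practice staining and scanning introduce a global,
monotone brightness shift that biases every spot quantity.  GIHM first
runs GIH equalization on both images (enhancing weak spots and moving
both toward a canonical distribution), then maps each test gray level to
the reference gray level whose cumulative distribution value is nearest
-- the discrete realization of ``v = f^{-1}(g(w))`` for continuous CDFs
``f`` (reference) and ``g`` (test).  The mapping is monotone, so the
relative ordering of pixel intensities is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .equalize import Distribution, GrayLevelMapping, apply_mapping, gihe
from .image import GrayImage

__all__ = ["MatchResult", "image_cdf", "nearest_cdf_mapping", "gihm"]


@dataclass(frozen=True)
class MatchResult:
    """Output of brightness matching a test image to a reference.

    ``reference_out`` is the (GIH-)equalized reference, ``test_out`` the
    matched test image whose gray histogram approximates the
    reference's.
    """

    reference_out: GrayImage
    test_out: GrayImage
    mapping: GrayLevelMapping
    cdf_reference: Distribution
    cdf_test: Distribution

    def __post_init__(self) -> None:
        if self.reference_out.levels != self.test_out.levels:
            raise ValueError("matched images must share a level count")


def image_cdf(img: GrayImage) -> Distribution:
    """Ordinary pixel-count gray-level distribution of an image."""
    counts = np.bincount(img.pixels.ravel(), minlength=img.levels)
    return Distribution.from_counts(counts)


def nearest_cdf_mapping(
    cdf_ref: Distribution, cdf_test: Distribution
) -> GrayLevelMapping:
    """Map each test level to the reference level with the nearest CDF value.

    For every test level ``w`` the reference level ``v`` minimizing
    ``|C_ref(v) - C_test(w)|`` is chosen; when several levels are
    equidistant (including runs of zero-mass levels sharing one CDF
    value) the smallest one wins, which keeps the map monotone and
    deterministic.
    """
    cr = cdf_ref.cdf
    ct = cdf_test.cdf
    if cr.shape != ct.shape:
        raise ValueError(
            f"CDF length mismatch: {cr.shape[0]} vs {ct.shape[0]}"
        )
    L = cr.shape[0]
    idx = np.searchsorted(cr, ct, side="left")
    hi = np.clip(idx, 0, L - 1)
    lo = np.clip(idx - 1, 0, L - 1)
    choose_lo = np.abs(cr[lo] - ct) <= np.abs(cr[hi] - ct)
    v = np.where(choose_lo, lo, hi)
    # canonicalize ties between equal CDF values to the smallest level
    v = np.searchsorted(cr, cr[v], side="left")
    return GrayLevelMapping(v)


def gihm(
    reference: GrayImage, test: GrayImage, *, apply_gihe: bool = True
) -> MatchResult:
    """Full brightness-correction pipeline for an image pair.

    GIHE is applied to the reference (``R -> I``) and to the test image
    (``T -> J``); the test result is then pushed through the
    nearest-CDF gray-level map so that its histogram matches the
    reference's (``J -> G``).  With ``apply_gihe=False`` the
    equalization stage is skipped and the result is plain histogram
    matching of ``T`` onto ``R`` (useful for ablation).
    """
    if reference.levels != test.levels:
        raise ValueError("reference and test must share a level count")
    if apply_gihe:
        ref_eq = gihe(reference).image
        test_eq = gihe(test).image
    else:
        ref_eq = reference
        test_eq = test
    cdf_ref = image_cdf(ref_eq)
    cdf_test = image_cdf(test_eq)
    mapping = nearest_cdf_mapping(cdf_ref, cdf_test)
    matched = apply_mapping(test_eq, mapping)
    return MatchResult(ref_eq, matched, mapping, cdf_ref, cdf_test)
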