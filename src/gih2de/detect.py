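"""Spot detection: h-dome centers and marker-controlled watershed contours.

These are the standard evaluation tools of 2DE image analysis, not the
contribution of this package; they exist so that quantification can run
end to end on real or synthetic gels.

Centers
    The image is lightly smoothed and subtracted from a morphological
    estimate of the spot-free background (a grayscale closing whose
    window exceeds the largest spot), yielding a drift-free depth map in
    which spots are bright peaks.  Peaks of prominence at least ``h``
    are found with the h-maxima transform (grayscale reconstruction),
    and each maximum is expanded to the connected cap of its h-dome
    above ``h / 2``, which serves as the spot-center pixel set.

Contours
    A marker-controlled watershed floods the smoothed image (spots are
    catchment basins) from the center markers plus one background
    marker; each basin is then trimmed to the connected component, around
    its deepest point, of pixels whose depth below the locally estimated
    background exceeds ``exp(-2)`` of the peak depth.  For an ideal
    Gaussian spot this contour is exactly the 2-sigma ellipse, the same
    support convention the synthetic generator uses for ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_maxima, reconstruction
from skimage.segmentation import watershed

from .image import GrayImage
from .quantify import CpsPair, SpotRecord

__all__ = ["DetectionParams", "hdome_centers", "watershed_contours", "pair_cps"]

_EDGE_FRACTION = np.exp(-2.0)  # depth fraction defining the spot contour


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detection parameters.

    ``h``: dome height in gray levels -- a spot must stand out from its
    surroundings by at least this much after smoothing.
    ``weak_threshold``: spots whose mean gray value exceeds this are
    flagged weak (close to the bright background).
    ``min_area``: minimum region pixel count.
    ``background_ring_width``: width of the local-background ring.
    ``smooth_sigma``: Gaussian pre-smoothing for center detection
    (0 disables).
    ``contour_smooth_sigma``: lighter smoothing used when tracing the
    region contour, so the traced boundary stays close to the
    unsmoothed spot extent.
    ``bg_window``: window (pixels) of the max-min filter that estimates
    the spot-free background surface; must exceed the largest spot
    diameter.
    """

    h: int = 10
    weak_threshold: float = 90.0
    min_area: int = 5
    background_ring_width: int = 3
    smooth_sigma: float = 1.0
    contour_smooth_sigma: float = 0.7
    bg_window: int = 41

    def __post_init__(self) -> None:
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.weak_threshold < 0:
            raise ValueError("weak_threshold must be non-negative")


def _smoothed(arr: np.ndarray, sigma: float) -> np.ndarray:
    a = arr.astype(np.float64)
    return ndi.gaussian_filter(a, sigma) if sigma > 0 else a


def hdome_centers(
    img: GrayImage, params: DetectionParams = DetectionParams()
) -> list[np.ndarray]:
    """Candidate spot-center regions, one ``(N, 2)`` coordinate array each.

    Only peaks (of the inverted image) with prominence >= ``h`` produce a
    center; a flat image or a spot shallower than ``h`` yields none.
    Centers are ordered by their peak position (row-major) so results
    are deterministic.
    """
    sm = _smoothed(img.pixels, params.smooth_sigma)
    # flatten the slowly varying background first (closing with a window
    # larger than any spot), otherwise broad drift basins masquerade as
    # prominent peaks of the inverted image
    w = params.bg_window
    bg_est = ndi.minimum_filter(ndi.maximum_filter(sm, size=w), size=w)
    depth = np.clip(bg_est - sm, 0.0, None)
    maxima = h_maxima(depth, params.h)
    if not maxima.any():
        return []
    dome = depth - reconstruction(depth - params.h, depth, method="dilation")
    caps, n = ndi.label(dome >= params.h / 2.0)
    centers: list[tuple[tuple[int, int], np.ndarray]] = []
    for lbl in range(1, n + 1):
        mask = caps == lbl
        if mask.all():
            continue  # a "dome" spanning the whole image is no peak
        peaks = maxima & mask
        if not peaks.any():
            continue
        coords = np.argwhere(mask)
        peak = tuple(np.argwhere(peaks)[0])
        centers.append((peak, coords))
    centers.sort(key=lambda t: t[0])
    return [coords for _, coords in centers]


def watershed_contours(
    img: GrayImage,
    centers: list[np.ndarray],
    params: DetectionParams = DetectionParams(),
) -> tuple[np.ndarray, list[SpotRecord]]:
    """Segment spot regions around the given centers.

    Returns a label image (0 = background, ``i + 1`` = region of
    ``centers[i]`` when it survives the area filter) and the
    corresponding :class:`SpotRecord` list with intensity statistics
    measured on the original image.  Spots whose trimmed region is
    smaller than ``min_area`` are discarded.
    """
    labels_out = np.zeros(img.shape, dtype=np.int32)
    if not centers:
        return labels_out, []

    sm = _smoothed(img.pixels, params.contour_smooth_sigma)

    # spot-free background surface: grayscale closing with a window
    # larger than any spot
    w = params.bg_window
    bg_est = ndi.minimum_filter(ndi.maximum_filter(sm, size=w), size=w)
    depth = np.clip(bg_est - sm, 0.0, None)

    markers = np.zeros(img.shape, dtype=np.int32)
    for i, coords in enumerate(centers):
        markers[coords[:, 0], coords[:, 1]] = i + 1
    bg_label = len(centers) + 1
    bg_mask = (depth <= 0.5) & (markers == 0)
    if not bg_mask.any():
        bg_mask = (sm >= sm.max()) & (markers == 0)
    markers[bg_mask] = bg_label
    basins = watershed(sm, markers)

    def _trace(basin, peak, depth_map, dmax):
        mask = basin & (depth_map >= dmax * _EDGE_FRACTION)
        comp, _ = ndi.label(mask)
        lbl = comp[peak[0], peak[1]]
        return (comp == lbl) if lbl else None

    # first pass against the (biased-high) closing estimate, second pass
    # against the unbiased median of a local background ring
    prelim: list[tuple[int, np.ndarray, np.ndarray]] = []
    for i, coords in enumerate(centers):
        basin = basins == i + 1
        cap_depth = depth[coords[:, 0], coords[:, 1]]
        peak = coords[np.argmax(cap_depth)]
        dmax = depth[peak[0], peak[1]]
        if dmax <= 0:
            continue
        region_mask = _trace(basin, peak, depth, dmax)
        if region_mask is not None:
            prelim.append((i, region_mask, peak))

    all_prelim = np.zeros(img.shape, dtype=bool)
    for _, region_mask, _ in prelim:
        all_prelim |= region_mask

    regions: list[tuple[int, np.ndarray, np.ndarray]] = []
    for i, region_mask, peak in prelim:
        ring = ndi.binary_dilation(region_mask, iterations=4) & ~all_prelim
        b_loc = np.median(sm[ring]) if ring.any() else bg_est[peak[0], peak[1]]
        local_depth = b_loc - sm
        dmax = local_depth[peak[0], peak[1]]
        if dmax <= 0:
            continue
        refined = _trace(basins == i + 1, peak, local_depth, dmax)
        if refined is None or refined.sum() < params.min_area:
            continue
        regions.append((i, refined, centers[i]))

    all_regions = np.zeros(img.shape, dtype=bool)
    for _, region_mask, _ in regions:
        all_regions |= region_mask

    records: list[SpotRecord] = []
    ring_iters = max(1, params.background_ring_width)
    for i, region_mask, cap_coords in regions:
        labels_out[region_mask] = i + 1
        ring = ndi.binary_dilation(region_mask, iterations=ring_iters)
        ring &= ~all_regions
        cap_in_region = cap_coords[
            region_mask[cap_coords[:, 0], cap_coords[:, 1]]
        ]
        if cap_in_region.shape[0] == 0:
            cap_in_region = np.argwhere(region_mask)[:1]
        rec = SpotRecord.measure(
            img,
            spot_id=i,
            center_pixels=cap_in_region,
            region_pixels=np.argwhere(region_mask),
            background_pixels=np.argwhere(ring),
        )
        mean = rec.mean_intensity
        records.append(
            SpotRecord(
                spot_id=rec.spot_id,
                center_pixels=rec.center_pixels,
                region_pixels=rec.region_pixels,
                background_pixels=rec.background_pixels,
                mean_intensity=mean,
                volume=rec.volume,
                is_weak=bool(mean > params.weak_threshold),
            )
        )
    return labels_out, records


def _centroids(spots: list[SpotRecord]) -> np.ndarray:
    if not spots:
        return np.zeros((0, 2))
    return np.array([s.region_pixels.mean(axis=0) for s in spots])


def match_spot_indices(
    spots_a: list[SpotRecord],
    spots_b: list[SpotRecord],
    max_pair_distance: float = 5.0,
) -> list[tuple[int, int]]:
    """Greedy mutual-nearest-centroid matching; returns record index pairs.

    Candidate pairs are consumed in order of increasing centroid
    distance up to ``max_pair_distance``, each record used at most once.
    """
    if not spots_a or not spots_b:
        return []
    ca = _centroids(spots_a)
    cb = _centroids(spots_b)
    dist = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=2)
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int]] = []
    for ia, ib in order:
        if dist[ia, ib] > max_pair_distance:
            break
        if ia in used_a or ib in used_b:
            continue
        used_a.add(int(ia))
        used_b.add(int(ib))
        matches.append((int(ia), int(ib)))
    return matches


def pair_cps(
    spots_a: list[SpotRecord],
    spots_b: list[SpotRecord],
    max_pair_distance: float = 5.0,
) -> tuple[list[CpsPair], list[SpotRecord], list[SpotRecord]]:
    """Pair spots across two images by mutual nearest centroid.

    Each pair's quantification error is computed from the two records'
    mean intensities.  Returns ``(pairs, unpaired_a, unpaired_b)``.
    """
    matches = match_spot_indices(spots_a, spots_b, max_pair_distance)
    pairs = [
        CpsPair(
            spot_id=spots_a[ia].spot_id,
            q_a=spots_a[ia].mean_intensity,
            q_b=spots_b[ib].mean_intensity,
        )
        for ia, ib in matches
    ]
    used_a = {ia for ia, _ in matches}
    used_b = {ib for _, ib in matches}
    unpaired_a = [s for i, s in enumerate(spots_a) if i not in used_a]
    unpaired_b = [s for i, s in enumerate(spots_b) if i not in used_b]
    return pairs, unpaired_a, unpaired_b
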