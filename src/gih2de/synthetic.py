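"""Synthetic 2DE-like gel images with known ground truth.

Real gels show a bright background that drifts slowly across the image,
dark roughly-Gaussian protein spots spanning a wide intensity range
(from saturated, high-abundance spots down to weak spots barely below
the background), and pixel noise.  Comparable gels of the same sample
additionally differ by a global monotone brightness shift.  The
generator renders exactly that structure, keeps every quantity in real
arithmetic until a single final quantization, and reports per-spot
ground truth so the full detection/quantification pipeline can be
scored without real images.

A spot's ground-truth *support* is the set of pixels where its rendered
depth below the local background exceeds ``exp(-2)`` of the peak depth
-- the 2-sigma ellipse for an unsaturated Gaussian, consistently wider
for spots deep enough to clip at gray level 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .image import GrayImage

__all__ = [
    "SpotSpec",
    "GelSpec",
    "ShiftSpec",
    "TrueSpot",
    "GroundTruth",
    "render_gel",
    "apply_shift",
    "make_pair",
]

_EDGE_FRACTION = np.exp(-2.0)


@dataclass(frozen=True)
class SpotSpec:
    """One Gaussian spot: center, depth (gray levels) and axis sigmas."""

    row: float
    col: float
    amplitude: float
    sigma_y: float
    sigma_x: float
    is_weak: bool = False


@dataclass(frozen=True)
class GelSpec:
    """Parameters of one synthetic gel.

    The defaults render a 512x512 8-bit gel with 40 spots -- 30 strong
    (deep, mostly saturated; mean gray below 90) and 10 weak (shallow;
    mean gray far above 90) -- on a background of 200 with a +-15
    low-order polynomial drift and additive Gaussian noise of sigma 2.
    """

    shape: tuple[int, int] = (512, 512)
    spots: tuple[SpotSpec, ...] = ()
    background: float = 200.0
    drift_amplitude: float = 15.0
    noise_sigma: float = 2.0
    levels: int = 256
    seed: int = 0

    @classmethod
    def random(
        cls,
        seed: int,
        *,
        shape: tuple[int, int] = (512, 512),
        n_strong: int = 30,
        n_weak: int = 10,
        strong_amplitude: tuple[float, float] = (460.0, 560.0),
        weak_amplitude: tuple[float, float] = (18.0, 35.0),
        strong_sigma: tuple[float, float] = (3.0, 6.0),
        weak_sigma: tuple[float, float] = (2.5, 4.0),
        min_separation: float = 45.0,
        margin: float = 30.0,
        **kwargs,
    ) -> "GelSpec":
        """Draw a spot layout with a minimum pairwise center distance."""
        rng = np.random.default_rng(seed)
        H, W = shape
        centers: list[tuple[float, float]] = []
        attempts = 0
        n_total = n_strong + n_weak
        while len(centers) < n_total:
            attempts += 1
            if attempts > 100000:
                raise RuntimeError("could not place spots; relax separation")
            r = rng.uniform(margin, H - margin)
            c = rng.uniform(margin, W - margin)
            if all(np.hypot(r - r0, c - c0) >= min_separation for r0, c0 in centers):
                centers.append((r, c))
        spots = []
        for i, (r, c) in enumerate(centers):
            weak = i >= n_strong
            lo, hi = weak_amplitude if weak else strong_amplitude
            slo, shi = weak_sigma if weak else strong_sigma
            spots.append(
                SpotSpec(
                    row=r,
                    col=c,
                    amplitude=float(rng.uniform(lo, hi)),
                    sigma_y=float(rng.uniform(slo, shi)),
                    sigma_x=float(rng.uniform(slo, shi)),
                    is_weak=weak,
                )
            )
        return cls(shape=shape, spots=tuple(spots), seed=seed, **kwargs)


@dataclass(frozen=True)
class ShiftSpec:
    """A global monotone brightness shift plus fresh noise.

    ``kind`` is one of ``offset``, ``gain``, ``gamma``, ``composed``;
    ``composed`` applies gamma, then gain, then offset.  Gain and gamma
    must be positive so the transform is monotone non-decreasing.
    """

    kind: str = "composed"
    offset: float = -20.0
    gain: float = 1.0
    gamma: float = 0.8
    noise_sigma: float = 2.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.kind not in {"offset", "gain", "gamma", "composed"}:
            raise ValueError(f"unknown shift kind {self.kind!r}")
        if self.kind in {"gain", "composed"} and self.gain <= 0:
            raise ValueError("gain must be positive for a monotone shift")
        if self.kind in {"gamma", "composed"} and self.gamma <= 0:
            raise ValueError("gamma must be positive for a monotone shift")

    def lut(self, levels: int) -> np.ndarray:
        """Real-valued transform of each input level (before clamping)."""
        v = np.arange(levels, dtype=np.float64)
        top = levels - 1
        if self.kind == "offset":
            return v + self.offset
        if self.kind == "gain":
            return self.gain * v
        if self.kind == "gamma":
            return top * (v / top) ** self.gamma
        return self.gain * top * (v / top) ** self.gamma + self.offset

    @classmethod
    def identity(cls) -> "ShiftSpec":
        return cls(kind="composed", offset=0.0, gain=1.0, gamma=1.0, noise_sigma=0.0)


@dataclass(frozen=True)
class TrueSpot:
    """Ground truth for one rendered spot."""

    spot_id: int
    row: float
    col: float
    amplitude: float
    sigma_y: float
    sigma_x: float
    is_weak: bool
    support: np.ndarray  # (N, 2) pixel coordinates
    true_mean: float  # mean of the noiseless render over the support
    true_volume: float


@dataclass(frozen=True)
class GroundTruth:
    spots: tuple[TrueSpot, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "spot_id": [s.spot_id for s in self.spots],
                "row": [s.row for s in self.spots],
                "col": [s.col for s in self.spots],
                "amplitude": [s.amplitude for s in self.spots],
                "sigma_y": [s.sigma_y for s in self.spots],
                "sigma_x": [s.sigma_x for s in self.spots],
                "is_weak": [s.is_weak for s in self.spots],
                "area": [s.support.shape[0] for s in self.spots],
                "true_mean": [s.true_mean for s in self.spots],
                "true_volume": [s.true_volume for s in self.spots],
            }
        )

    def label_image(self, shape: tuple[int, int]) -> np.ndarray:
        lab = np.zeros(shape, dtype=np.int32)
        for s in self.spots:
            lab[s.support[:, 0], s.support[:, 1]] = s.spot_id + 1
        return lab


def _quantize(field_vals: np.ndarray, levels: int) -> np.ndarray:
    out = np.floor(field_vals + 0.5)
    np.clip(out, 0, levels - 1, out=out)
    return out.astype(np.uint8 if levels <= 256 else np.uint16)


def _drift_surface(shape: tuple[int, int], amplitude: float, rng) -> np.ndarray:
    """Low-order 2-D polynomial drift scaled to a peak magnitude."""
    H, W = shape
    y = np.linspace(-1.0, 1.0, H)[:, None]
    x = np.linspace(-1.0, 1.0, W)[None, :]
    coef = rng.uniform(-1.0, 1.0, size=5)
    surf = coef[0] * x + coef[1] * y + coef[2] * x * y + coef[3] * x**2 + coef[4] * y**2
    peak = np.abs(surf).max()
    if peak > 0 and amplitude > 0:
        surf *= amplitude / peak
    else:
        surf = np.zeros(shape)
    return surf


def render_gel(spec: GelSpec) -> tuple[GrayImage, GroundTruth]:
    """Render one gel and its ground truth.

    The noiseless field is background + drift minus the sum of Gaussian
    spots, clamped to the gray range; noise is added and the result is
    quantized once.  Ground-truth means and volumes are measured on the
    noiseless clamped field over each spot's support.
    """
    H, W = spec.shape
    rng = np.random.default_rng(spec.seed)
    bg_surface = spec.background + _drift_surface(spec.shape, spec.drift_amplitude, rng)
    clean = bg_surface.copy()

    windows: list[tuple[slice, slice, np.ndarray]] = []
    for s in spec.spots:
        ry = 4.0 * s.sigma_y
        rx = 4.0 * s.sigma_x
        if not (0 <= s.row < H and 0 <= s.col < W):
            raise ValueError(f"spot center ({s.row}, {s.col}) outside the image")
        y0, y1 = int(np.floor(s.row - ry)), int(np.ceil(s.row + ry)) + 1
        x0, x1 = int(np.floor(s.col - rx)), int(np.ceil(s.col + rx)) + 1
        y0, y1 = max(y0, 0), min(y1, H)
        x0, x1 = max(x0, 0), min(x1, W)
        yy = np.arange(y0, y1, dtype=np.float64)[:, None]
        xx = np.arange(x0, x1, dtype=np.float64)[None, :]
        profile = s.amplitude * np.exp(
            -((yy - s.row) ** 2) / (2 * s.sigma_y**2)
            - ((xx - s.col) ** 2) / (2 * s.sigma_x**2)
        )
        clean[y0:y1, x0:x1] -= profile
        windows.append((slice(y0, y1), slice(x0, x1), profile))

    np.clip(clean, 0, spec.levels - 1, out=clean)

    truths: list[TrueSpot] = []
    for i, (s, (sy, sx, profile)) in enumerate(zip(spec.spots, windows)):
        # the spot's own depth, clipped by what the gray range can show
        local_bg = bg_surface[sy, sx]
        depth = np.minimum(profile, local_bg)
        peak = depth.max()
        mask = depth >= peak * _EDGE_FRACTION
        coords = np.argwhere(mask)
        coords[:, 0] += sy.start
        coords[:, 1] += sx.start
        vals = clean[coords[:, 0], coords[:, 1]]
        truths.append(
            TrueSpot(
                spot_id=i,
                row=s.row,
                col=s.col,
                amplitude=s.amplitude,
                sigma_y=s.sigma_y,
                sigma_x=s.sigma_x,
                is_weak=s.is_weak,
                support=coords,
                true_mean=float(vals.mean()),
                true_volume=float(vals.sum()),
            )
        )

    noisy = clean + rng.normal(0.0, spec.noise_sigma, size=spec.shape) \
        if spec.noise_sigma > 0 else clean
    img = GrayImage(_quantize(noisy, spec.levels), spec.levels)
    return img, GroundTruth(tuple(truths))


def apply_shift(img: GrayImage, shift: ShiftSpec) -> GrayImage:
    """Apply a global monotone brightness shift plus fresh noise."""
    lut = shift.lut(img.levels)
    if (np.diff(lut) < 0).any():
        raise ValueError("shift must be monotone non-decreasing")
    out = lut[img.pixels]
    if shift.noise_sigma > 0:
        rng = np.random.default_rng(shift.seed)
        out = out + rng.normal(0.0, shift.noise_sigma, size=out.shape)
    return GrayImage(_quantize(out, img.levels), img.levels)


def make_pair(
    spec: GelSpec, shift: ShiftSpec
) -> tuple[GrayImage, GrayImage, GroundTruth]:
    """Render a reference gel and a brightness-shifted test copy.

    Both images share the spot geometry exactly, so every ground-truth
    spot is a true corresponding-protein-spot pair.
    """
    reference, truth = render_gel(spec)
    test = apply_shift(reference, shift)
    return reference, test, truth


def default_pair(seed: int) -> tuple[GrayImage, GrayImage, GroundTruth]:
    """The study-condition fixture: default gel, gamma 0.8 + offset -20 shift."""
    spec = GelSpec.random(seed=seed)
    shift = replace(ShiftSpec(), seed=seed + 1_000_003)
    return make_pair(spec, shift)
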