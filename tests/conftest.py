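import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gih2de import GrayImage

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_image(rng, max_side=32, levels=256) -> GrayImage:
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    return GrayImage(rng.integers(0, levels, size=(h, w)), levels)


def gih_oracle(img: GrayImage, include_center: bool = True) -> np.ndarray:
    """Naive per-pixel interval accumulation over the clipped 3x3 window."""
    a = img.pixels
    H, W = a.shape
    counts = np.zeros(img.levels, dtype=np.int64)
    for y in range(H):
        for x in range(W):
            vals = []
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if not include_center and dy == 0 and dx == 0:
                        continue
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < H and 0 <= xx < W:
                        vals.append(a[yy, xx])
            if not vals:
                vals = [a[y, x]]
            counts[min(vals) : max(vals) + 1] += 1
    return counts


def nearest_cdf_oracle(cdf_ref: np.ndarray, cdf_test: np.ndarray) -> np.ndarray:
    """Exhaustive argmin over all (v, w) pairs; ties -> smallest v."""
    out = np.empty(len(cdf_test), dtype=np.int64)
    for w, g in enumerate(cdf_test):
        out[w] = int(np.argmin(np.abs(cdf_ref - g)))
    return out


def random_distribution(rng, levels):
    from gih2de import Distribution

    counts = rng.integers(0, 10, size=levels)
    if counts.sum() == 0:
        counts[int(rng.integers(0, levels))] = 1
    return Distribution.from_counts(counts)
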