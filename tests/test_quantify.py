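"""Spot metrics: gray-value difference, volume, normalization, CPS error."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gih2de import (
    CpsPair,
    Distribution,
    GrayImage,
    SpotRecord,
    average_cps_error,
    compute_distribution,
    compute_gih,
    enhancement_heatmap,
    gray_value_difference,
    normalize_image,
    quantification_error,
    spot_volume,
)


def make_spot(img_vals, center, region, background, spot_id=0):
    return SpotRecord.measure(
        np.asarray(img_vals), spot_id, np.array(center), np.array(region),
        np.array(background),
    )


@pytest.fixture
def grid_image():
    return np.arange(100).reshape(10, 10)


class TestGrayValueDifference:
    def test_dark_spot_on_bright_background(self):
        img = np.full((5, 5), 200)
        img[2, 2] = 50
        spot = make_spot(img, [[2, 2]], [[2, 2]], [[0, 0], [0, 1]])
        assert gray_value_difference(img, spot) == -150

    def test_zero_when_equal(self):
        img = np.full((3, 3), 80)
        spot = make_spot(img, [[1, 1]], [[1, 1]], [[0, 0]])
        assert gray_value_difference(img, spot) == 0

    def test_hand_computed_means(self):
        img = np.zeros((2, 5), dtype=int)
        img[0, :2] = [40, 60]
        img[1, :3] = [100, 120, 140]
        spot = make_spot(
            img, [[0, 0], [0, 1]], [[0, 0], [0, 1]],
            [[1, 0], [1, 1], [1, 2]],
        )
        assert gray_value_difference(img, spot) == pytest.approx(50 - 120)

    def test_empty_background_rejected(self):
        img = np.full((3, 3), 10)
        spot = make_spot(img, [[1, 1]], [[1, 1]], np.zeros((0, 2), dtype=int))
        with pytest.raises(ValueError):
            gray_value_difference(img, spot)


class TestSpotVolume:
    def test_constant_region(self):
        img = np.full((4, 4), 50)
        region = [[i // 4, i % 4] for i in range(10)]
        spot = make_spot(img, [region[0]], region, [[3, 3]])
        assert spot_volume(img, spot) == (10, 50.0, 500.0)

    def test_single_pixel(self):
        img = np.array([[0, 0], [0, 77]])
        spot = make_spot(img, [[1, 1]], [[1, 1]], [[0, 0]])
        assert spot_volume(img, spot) == (1, 77.0, 77.0)

    def test_hand_computed(self):
        img = np.array([[10, 20, 30]])
        spot = make_spot(
            img, [[0, 0]], [[0, 0], [0, 1], [0, 2]], np.zeros((0, 2), dtype=int)
        )
        assert spot_volume(img, spot) == (3, 20.0, 60.0)

    @given(st.integers(0, 2**31 - 1))
    def test_volume_identity_on_random_regions(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(16, 16))
        n = int(rng.integers(1, 40))
        flat = rng.choice(256, size=n, replace=False)
        region = np.stack([flat // 16, flat % 16], axis=1)
        spot = make_spot(img, region[:1], region, np.zeros((0, 2), dtype=int))
        area, mean, volume = spot_volume(img, spot)
        assert volume == pytest.approx(area * mean, abs=1e-9)
        assert volume == pytest.approx(
            img[region[:, 0], region[:, 1]].sum(), abs=1e-9
        )


class TestSpotRecordInvariants:
    def test_center_outside_region_rejected(self):
        with pytest.raises(ValueError):
            make_spot(np.zeros((4, 4)), [[0, 0]], [[1, 1]], [[2, 2]])

    def test_background_overlap_rejected(self):
        with pytest.raises(ValueError):
            make_spot(np.zeros((4, 4)), [[1, 1]], [[1, 1]], [[1, 1]])

    def test_inconsistent_volume_rejected(self):
        with pytest.raises(ValueError):
            SpotRecord(
                spot_id=0,
                center_pixels=np.array([[1, 1]]),
                region_pixels=np.array([[1, 1]]),
                background_pixels=np.zeros((0, 2), dtype=int),
                mean_intensity=10.0,
                volume=99.0,
            )


class TestNormalizeImage:
    def test_target_moments(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, size=(20, 30))
            out = normalize_image(img)
            assert out.mean() == pytest.approx(127.0, abs=1e-9)
            assert out.var() == pytest.approx(127.0, abs=1e-9)

    def test_idempotent(self, rng):
        img = rng.integers(0, 256, size=(15, 15))
        once = normalize_image(img)
        np.testing.assert_allclose(normalize_image(once), once, atol=1e-9)

    def test_two_pixel_example(self):
        out = normalize_image(np.array([[0, 2]]))
        np.testing.assert_allclose(
            np.sort(out.ravel()),
            [127 - np.sqrt(127), 127 + np.sqrt(127)],
            atol=1e-12,
        )

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            normalize_image(np.full((5, 5), 9))


class TestQuantificationError:
    def test_twenty_percent_example(self):
        assert quantification_error(110, 90) == pytest.approx(20.0)

    def test_zero_at_equality_and_antisymmetry(self):
        assert quantification_error(55, 55) == 0.0
        assert quantification_error(90, 110) == -quantification_error(110, 90)

    def test_non_positive_sum_rejected(self):
        with pytest.raises(ValueError):
            quantification_error(0.0, 0.0)

    @given(
        st.floats(0.01, 1e6), st.floats(0.01, 1e6)
    )
    def test_bounded_by_200_percent(self, qa, qb):
        assert abs(quantification_error(qa, qb)) <= 200.0


class TestCpsPairAndAverage:
    def test_pair_sign_behavior(self):
        assert CpsPair(0, 100.0, 100.0).d_percent == 0.0
        assert CpsPair(0, 110.0, 90.0).d_percent == pytest.approx(
            -CpsPair(0, 90.0, 110.0).d_percent
        )

    def test_average_absolute_convention(self):
        pairs = [CpsPair(0, 102.0, 98.0), CpsPair(1, 99.0, 101.0)]
        # signed errors are +4% and -2%; the average uses magnitudes
        assert pairs[0].d_percent == pytest.approx(4.0)
        assert pairs[1].d_percent == pytest.approx(-2.0)
        assert average_cps_error(pairs) == pytest.approx(3.0)

    def test_single_pair_and_zero(self):
        assert average_cps_error([CpsPair(0, 90.0, 110.0)]) == pytest.approx(20.0)
        assert average_cps_error([CpsPair(0, 5.0, 5.0)]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_cps_error([])


class TestEnhancementHeatmap:
    def test_uniform_pdf_constant_map(self, rng):
        img = GrayImage(rng.integers(0, 256, size=(6, 6)), 256)
        dist = Distribution.from_counts(np.ones(256))
        assert (enhancement_heatmap(img, dist) == 1 / 256).all()

    def test_constant_image(self):
        img = GrayImage(np.full((4, 4), 9), 256)
        dist = Distribution.from_counts(np.bincount(img.pixels.ravel(), minlength=256))
        assert (enhancement_heatmap(img, dist) == 1.0).all()

    def test_2x2_gih_density(self):
        img = GrayImage(np.array([[0, 1], [2, 3]]), 256)
        dist = compute_distribution(compute_gih(img))
        np.testing.assert_allclose(enhancement_heatmap(img, dist), 0.25)
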