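"""Gradient interval histogram construction and GIH equalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gih2de import (
    Distribution,
    GrayImage,
    GrayLevelMapping,
    apply_mapping,
    compute_distribution,
    compute_gih,
    equalization_mapping,
    gihe,
    mapping_slope,
)
from conftest import gih_oracle, random_image


@pytest.fixture
def example_2x2():
    return GrayImage(np.array([[0, 1], [2, 3]]), 256)


class TestComputeGih:
    def test_2x2_whole_image_window(self, example_2x2):
        # every pixel's window is the whole image: interval [0, 3] four times
        gih = compute_gih(example_2x2)
        assert gih.counts[:4].tolist() == [4, 4, 4, 4]
        assert gih.counts[4:].sum() == 0
        assert gih.total() == 16

    def test_constant_image_equals_plain_histogram(self):
        img = GrayImage(np.full((7, 5), 42), 256)
        gih = compute_gih(img)
        assert gih.counts[42] == 35
        assert gih.total() == 35

    @pytest.mark.parametrize("include_center", [True, False])
    def test_matches_bruteforce_oracle(self, rng, include_center):
        for _ in range(30):
            img = random_image(rng, max_side=16, levels=int(rng.choice([8, 256])))
            got = compute_gih(img, include_center=include_center)
            np.testing.assert_array_equal(
                got.counts, gih_oracle(img, include_center)
            )

    def test_binary_extremes_fill_all_bins(self, rng):
        img = GrayImage(rng.choice([0, 255], size=(8, 8)), 256)
        gih = compute_gih(img)
        oracle = gih_oracle(img)
        np.testing.assert_array_equal(gih.counts, oracle)
        # any pixel seeing both extremes contributes to every bin
        mixed = oracle[1]  # bins 1..254 only receive full-range intervals
        assert (oracle[1:255] == mixed).all()

    def test_conservation(self, rng):
        from scipy import ndimage as ndi

        img = random_image(rng, max_side=20)
        a = img.pixels.astype(int)
        kmin = ndi.minimum_filter(a, size=3, mode="nearest")
        kmax = ndi.maximum_filter(a, size=3, mode="nearest")
        assert compute_gih(img).total() == int((kmax - kmin + 1).sum())

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            GrayImage(np.zeros((0, 4), dtype=int))

    def test_single_pixel_image(self):
        gih = compute_gih(GrayImage(np.array([[7]]), 256))
        assert gih.counts[7] == 1 and gih.total() == 1
        gih_ex = compute_gih(
            GrayImage(np.array([[7]]), 256), include_center=False
        )
        assert gih_ex.counts[7] == 1  # no neighbors: pixel's own level counts


class TestDistribution:
    def test_from_2x2_counts(self, example_2x2):
        dist = compute_distribution(compute_gih(example_2x2))
        np.testing.assert_allclose(dist.pdf[:4], 0.25)
        np.testing.assert_allclose(dist.cdf[:5], [0.25, 0.5, 0.75, 1.0, 1.0])

    def test_single_bin(self):
        from gih2de.equalize import GradientIntervalHistogram

        counts = np.zeros(256, dtype=int)
        counts[9] = 50
        dist = compute_distribution(GradientIntervalHistogram(counts, (5, 10)))
        assert dist.pdf[9] == 1.0
        assert (dist.cdf[:9] == 0).all() and (dist.cdf[9:] == 1.0).all()

    def test_uniform_counts(self):
        dist = Distribution.from_counts(np.full(256, 3))
        np.testing.assert_allclose(dist.pdf, 1 / 256)
        np.testing.assert_allclose(dist.cdf, (np.arange(256) + 1) / 256)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            Distribution.from_counts(np.zeros(256))

    @given(st.integers(0, 2**31 - 1))
    def test_normalization_invariants(self, seed):
        rng = np.random.default_rng(seed)
        dist = Distribution.from_counts(rng.integers(0, 100, size=64) + 0.0)
        assert abs(dist.pdf.sum() - 1.0) < 1e-12
        assert (np.diff(dist.cdf) >= -1e-12).all()
        assert abs(dist.cdf[-1] - 1.0) < 1e-12


class TestEqualizationMapping:
    def test_worked_example(self, example_2x2):
        dist = compute_distribution(compute_gih(example_2x2))
        table = equalization_mapping(dist).table
        assert table[:4].tolist() == [64, 128, 191, 255]
        assert (table[4:] == 255).all()

    def test_step_cdf_saturates(self):
        pdf = np.zeros(256)
        pdf[100] = 1.0
        table = equalization_mapping(Distribution(pdf, np.cumsum(pdf))).table
        assert (table[:100] == 0).all() and (table[100:] == 255).all()

    def test_uniform_pdf_near_identity(self):
        dist = Distribution.from_counts(np.ones(256))
        table = equalization_mapping(dist).table
        expected = np.floor(255 * (np.arange(256) + 1) / 256 + 0.5)
        np.testing.assert_array_equal(table, expected)

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_for_random_histograms(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, size=int(rng.integers(2, 300)))
        if counts.sum() == 0:
            counts[0] = 1
        table = equalization_mapping(Distribution.from_counts(counts)).table
        assert (np.diff(table) >= 0).all()

    def test_slope_identity_within_one_level(self, rng):
        # table[k] - table[k-1] tracks 255 * pdf[k] up to integer rounding
        for _ in range(20):
            img = random_image(rng, max_side=24)
            dist = compute_distribution(compute_gih(img))
            table = equalization_mapping(dist).table
            diff = np.diff(table.astype(float))
            assert np.abs(diff - 255 * dist.pdf[1:]).max() <= 1.0


class TestApplyMappingAndGihe:
    def test_identity_mapping(self, rng):
        img = random_image(rng)
        out = apply_mapping(img, GrayLevelMapping.identity(img.levels))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_2x2_full_pipeline(self, example_2x2):
        out = gihe(example_2x2).image
        assert out.pixels.tolist() == [[64, 128], [191, 255]]

    def test_constant_image_becomes_white(self):
        out = gihe(GrayImage(np.full((6, 6), 17), 256)).image
        assert (out.pixels == 255).all()

    def test_level_count_mismatch_rejected(self, rng):
        img = random_image(rng, levels=8)
        with pytest.raises(ValueError):
            apply_mapping(img, GrayLevelMapping.identity(256))

    def test_all_zero_image_maps_to_table0(self):
        table = np.clip(np.arange(256) + 5, 0, 255)
        out = apply_mapping(
            GrayImage(np.zeros((3, 3), dtype=int)), GrayLevelMapping(table)
        )
        assert (out.pixels == 5).all()

    def test_occupied_levels_are_mapped_levels(self, rng):
        img = random_image(rng)
        result = gihe(img)
        got = np.unique(result.image.pixels)
        expected = np.unique(result.mapping.table[np.unique(img.pixels)])
        np.testing.assert_array_equal(got, expected)

    def test_rank_preservation(self, rng):
        img = random_image(rng)
        out = gihe(img).image
        a, b = img.pixels.ravel(), out.pixels.ravel()
        order = np.argsort(a, kind="stable")
        assert (np.diff(b[order]) >= 0).all()


class TestMappingSlope:
    def test_unit_slope_at_density_one_over_255(self):
        # p(k) = 1/255 is the break-even density: slope exactly 1
        pdf = np.zeros(256)
        pdf[1] = 1 / 255.0
        pdf[0] = 1 - pdf[1]
        dist = Distribution(pdf, np.cumsum(pdf))
        assert mapping_slope(dist, 1) == pytest.approx(1.0, abs=1e-12)

    def test_zero_and_double_density(self):
        pdf = np.zeros(256)
        pdf[0] = 1 - 2 / 255.0
        pdf[10] = 2 / 255.0
        dist = Distribution(pdf, np.cumsum(pdf))
        assert mapping_slope(dist, 5) == 0.0
        assert mapping_slope(dist, 10) == pytest.approx(2.0)

    def test_out_of_range_rejected(self):
        dist = Distribution.from_counts(np.ones(256))
        with pytest.raises(ValueError):
            mapping_slope(dist, 0)
        with pytest.raises(ValueError):
            mapping_slope(dist, 256)
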