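"""Intensity derivation, level classification and ROI measurement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ihctasc.config import LevelThresholds, TEN_HPF_AREA_UM2
from ihctasc.errors import ConfigurationError, DegenerateRoiError, FormatError
from ihctasc.quant import (
    ARTIFACT_RGB,
    IntensityImage,
    RegionOfInterest,
    classify_levels,
    compute_intensity_image,
    detect_artifacts,
    measure_roi,
)
from ihctasc.synthetic import _render_rgb


def make_image(values, pixel_size=1.0):
    return IntensityImage(np.asarray(values, dtype=np.uint8), pixel_size)


def full_roi(shape, compartment="tumor"):
    return RegionOfInterest(np.ones(shape, dtype=bool), compartment)


class TestThresholds:
    def test_band_boundaries(self):
        """Boundary pixel values fall in the published bands."""
        thr = LevelThresholds()
        values = [70, 71, 100, 101, 130, 131, 175, 176]
        expected = [4, 3, 3, 2, 2, 1, 1, 0]
        assert [thr.level_of(v) for v in values] == expected

    def test_bands_partition_the_byte_range(self):
        thr = LevelThresholds()
        seen = {}
        for v in range(256):
            lvl = thr.level_of(v)
            assert v not in seen
            seen[v] = lvl
        assert len(seen) == 256

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            LevelThresholds(level1=(120, 175))

    def test_gap_rejected(self):
        with pytest.raises(ValueError):
            LevelThresholds(level1=(132, 175))


class TestClassifyLevels:
    def test_all_background_image(self):
        img = make_image(np.full((10, 10), 255))
        assert (classify_levels(img) == 0).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_bruteforce_interval_membership(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 256, size=(20, 20))
        img = make_image(values)
        levels = classify_levels(img)
        thr = LevelThresholds()
        brute = np.vectorize(thr.level_of)(values)
        assert (levels == brute).all()

    def test_monotone_in_stain_strength(self):
        """Lowering a pixel value (stronger brown) never lowers its level."""
        thr = LevelThresholds()
        lv = [thr.level_of(v) for v in range(256)]
        assert all(lv[i] >= lv[i + 1] for i in range(255))


class TestComputeIntensity:
    def test_white_pixel_is_background(self):
        rgb = np.full((2, 2, 3), 255, dtype=np.uint8)
        img = compute_intensity_image(rgb)
        assert (img.values == 255).all()

    def test_passthrough_identity(self):
        values = np.arange(100, dtype=np.uint8).reshape(10, 10)
        img = compute_intensity_image(values, method="passthrough")
        assert (img.values == values).all()

    def test_passthrough_requires_single_channel(self):
        with pytest.raises(FormatError):
            compute_intensity_image(np.zeros((4, 4, 3), np.uint8), method="passthrough")

    def test_hdab_requires_rgb(self):
        with pytest.raises(FormatError):
            compute_intensity_image(np.zeros((4, 4), np.uint8))

    def test_monotone_in_dab_optical_density(self):
        """Pixels rendered at increasing DAB optical density receive
        non-increasing (mostly decreasing) intensity values."""
        target = np.arange(0, 256, 8, dtype=np.uint8).reshape(1, -1)
        rgb = _render_rgb(target)
        got = compute_intensity_image(rgb).values[0].astype(int)
        diffs = np.diff(got)
        assert (diffs >= 0).all()  # od decreases along the row
        assert got[-1] > got[0]


class TestDetectArtifacts:
    def test_clean_image_empty_mask(self):
        rgb = np.full((5, 5, 3), 128, dtype=np.uint8)
        assert not detect_artifacts(rgb).any()

    def test_saturated_white_roi_fully_flagged(self):
        rgb = np.full((5, 5, 3), 255, dtype=np.uint8)
        roi = full_roi((5, 5))
        assert (detect_artifacts(rgb, roi) == roi.mask).all()

    def test_reserved_color_and_debris_flagged(self):
        rgb = np.full((2, 3, 3), 128, dtype=np.uint8)
        rgb[0, 0] = ARTIFACT_RGB
        rgb[1, 2] = (3, 3, 3)
        mask = detect_artifacts(rgb)
        assert mask.sum() == 2 and mask[0, 0] and mask[1, 2]


class TestMeasureRoi:
    def test_hand_arithmetic_normalization(self):
        """500 of 10,000 one-micron pixels at level 4 -> 118,500 µm² per
        2.37 mm² (500 x 2,370,000 / 10,000)."""
        values = np.full((100, 100), 200, dtype=np.uint8)
        values.flat[:500] = 60
        res = measure_roi(make_image(values), full_roi((100, 100)))
        assert res.level_areas[4] == 500.0
        assert res.total_positive_area == 500.0
        assert res.roi_area == 10_000.0
        assert res.normalized_total == pytest.approx(118_500.0)

    def test_uniform_image_mean_intensity(self):
        values = np.full((10, 10), 142, dtype=np.uint8)
        res = measure_roi(make_image(values), full_roi((10, 10)))
        assert res.mean_intensity == 142.0

    def test_replication_invariance_of_normalization(self):
        """Tiling the same composition into a larger ROI leaves the
        normalized areas unchanged."""
        rng = np.random.default_rng(5)
        tile = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
        big = np.tile(tile, (2, 2))
        small_res = measure_roi(make_image(tile), full_roi((40, 40)))
        big_res = measure_roi(make_image(big), full_roi((80, 80)))
        for lvl in range(5):
            assert big_res.normalized_areas[lvl] == pytest.approx(
                small_res.normalized_areas[lvl]
            )
        assert big_res.normalized_total == pytest.approx(small_res.normalized_total)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), artifact_frac=st.floats(0, 0.5))
    def test_area_conservation(self, seed, artifact_frac):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 256, size=(30, 30)).astype(np.uint8)
        artifacts = rng.random((30, 30)) < artifact_frac
        roi = full_roi((30, 30))
        try:
            res = measure_roi(make_image(values), roi, artifact_mask=artifacts)
        except DegenerateRoiError:
            assert artifacts.all()
            return
        total_levels = sum(res.level_areas.values())
        assert total_levels + res.artifact_area == pytest.approx(res.roi_area)

    def test_mean_intensity_decreases_when_a_pixel_darkens(self):
        values = np.full((10, 10), 150, dtype=np.uint8)
        base = measure_roi(make_image(values), full_roi((10, 10)))
        values2 = values.copy()
        values2[0, 0] = 40
        darker = measure_roi(make_image(values2), full_roi((10, 10)))
        assert darker.mean_intensity < base.mean_intensity
        assert 0 <= darker.mean_intensity <= 255

    def test_fully_artifact_roi_is_degenerate(self):
        values = np.full((5, 5), 100, dtype=np.uint8)
        with pytest.raises(DegenerateRoiError):
            measure_roi(
                make_image(values),
                full_roi((5, 5)),
                artifact_mask=np.ones((5, 5), bool),
            )

    def test_pixel_size_scales_areas(self):
        values = np.full((10, 10), 60, dtype=np.uint8)
        res = measure_roi(make_image(values, pixel_size=2.0), full_roi((10, 10)))
        assert res.roi_area == 400.0
        assert res.level_areas[4] == 400.0

    def test_incongruent_shapes_rejected(self):
        values = np.full((5, 5), 100, dtype=np.uint8)
        with pytest.raises(FormatError):
            measure_roi(make_image(values), full_roi((6, 6)))
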