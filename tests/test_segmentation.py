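"""Segmentation: thresholding, geometry recovery, area measurement."""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pytest
from skimage.filters import threshold_otsu

import folliscreen as fs
from folliscreen.errors import (
    BeadClippedError,
    BeadNotFoundError,
    DegenerateImageError,
    FollicleNotFoundError,
    GeometryError,
    MultipleBeadsError,
    UnevenIlluminationError,
)
from folliscreen.synthetic import SyntheticParams, generate_micrograph


def _two_level_image(lo=50, hi=200, frac_hi=0.6, side=64) -> fs.Micrograph:
    px = np.full(side * side, lo, np.uint8)
    n_hi = int(side * side * frac_hi)
    px[:n_hi] = hi
    rng = np.random.default_rng(0)
    rng.shuffle(px)
    return fs.Micrograph(px.reshape(side, side), 1.0)


class TestEstimateThreshold:
    def test_two_level_image_separated_exactly(self):
        """Brute-force scan oracle: some threshold separates the two levels
        perfectly, and the estimate is one of them, strictly inside (50, 200)."""
        img = _two_level_image()
        t = fs.estimate_threshold(img)
        assert 50 < t < 200
        # oracle: exhaustive scan over all 256 candidate levels
        px = img.pixels
        perfect = [
            c for c in range(256)
            if np.array_equal(px > c, px == 200)
        ]
        assert perfect, "oracle found no separating level"
        assert min(perfect) <= t <= max(perfect)

    def test_matches_library_otsu_class_split_on_noisy_image(self):
        """On a realistic noisy micrograph our plateau-midpoint Otsu induces
        the same pixel partition as scikit-image's Otsu."""
        img, _ = generate_micrograph(SyntheticParams(seed=21))
        ours = fs.estimate_threshold(img)
        theirs = threshold_otsu(img.pixels)
        agree = ((img.pixels > ours) == (img.pixels > theirs)).mean()
        assert agree >= 0.999

    def test_constant_image_raises(self):
        img = fs.Micrograph(np.full((64, 64), 128, np.uint8), 1.0)
        with pytest.raises(DegenerateImageError, match="no separable classes"):
            fs.estimate_threshold(img)

    def test_synthetic_pixels_classified_against_truth(self):
        img, truth = generate_micrograph(SyntheticParams(seed=3))
        t = fs.estimate_threshold(img)
        agree = ((img.pixels > t) == truth.degraded_map()).mean()
        assert agree >= 0.99

    def test_uneven_illumination_rejected(self, small_params):
        img, _ = generate_micrograph(replace(small_params, illumination_gradient=0.5))
        bead = fs.BeadGeometry(center=small_params.bead_center,
                               radius=small_params.bead_radius)
        with pytest.raises(UnevenIlluminationError, match="uneven illumination"):
            fs.estimate_threshold(img, bead=bead)
        # an evenly exposed image passes the same gate
        img2, _ = generate_micrograph(small_params)
        assert fs.estimate_threshold(img2, bead=bead) > 0


class TestBinarize:
    def test_bright_is_degraded_convention(self):
        tile = np.array([[10, 250], [250, 10]], np.uint8)
        img = fs.Micrograph(np.tile(tile, (32, 32)), 1.0)
        mask = fs.binarize(img, 128)
        assert np.array_equal(mask.degraded, img.pixels > 128)
        inverted = fs.binarize(img, 128, invert=True)
        assert np.array_equal(inverted.degraded, ~mask.degraded)

    def test_all_pixels_above_threshold_all_degraded(self):
        img = fs.Micrograph(np.full((64, 64), 200, np.uint8), 1.0)
        assert fs.binarize(img, 100).degraded.all()

    def test_threshold_outside_bit_depth_rejected(self):
        img = fs.Micrograph(np.full((64, 64), 200, np.uint8), 1.0)
        with pytest.raises(ValueError, match="intensity range"):
            fs.binarize(img, 300)

    def test_mask_agrees_with_generator_truth(self, small_params):
        img, truth = generate_micrograph(small_params)
        mask = fs.binarize(img, fs.estimate_threshold(img))
        agree = (mask.degraded == truth.degraded_map()).mean()
        assert agree >= 0.99


class TestMicrographValidation:
    @pytest.mark.parametrize(
        "pixels, mpp",
        [
            (np.zeros((32, 32), np.uint8), 1.0),  # too small
            (np.zeros((64, 64), np.float64), 1.0),  # wrong dtype
            (np.zeros((64, 64, 3), np.uint8), 1.0),  # not 2-D
            (np.zeros((64, 64), np.uint8), -1.0),  # bad calibration
            (np.zeros((64, 64), np.uint8), float("nan")),
        ],
    )
    def test_invalid_inputs_rejected(self, pixels, mpp):
        with pytest.raises(ValueError):
            fs.Micrograph(pixels, mpp)


class TestLocateBead:
    def test_recovers_center_and_radius(self):
        img, _ = generate_micrograph(SyntheticParams(seed=9))
        bead = fs.locate_bead(img)
        assert math.hypot(bead.center[0] - 256, bead.center[1] - 256) <= 3
        assert abs(bead.radius - 200) <= 6

    def test_no_contrast_raises(self):
        img = fs.Micrograph(np.full((64, 64), 50, np.uint8), 1.0)
        with pytest.raises(BeadNotFoundError):
            fs.locate_bead(img)

    def test_two_beads_rejected(self, small_params):
        a, _ = generate_micrograph(small_params)
        b, _ = generate_micrograph(replace(small_params, seed=12))
        img = fs.Micrograph(np.hstack([a.pixels, b.pixels]), 1.0)
        with pytest.raises(MultipleBeadsError):
            fs.locate_bead(img)

    def test_bead_clipped_flagged_or_allowed(self):
        p = SyntheticParams(seed=4, bead_radius=400.0, degradation_radius=155.0)
        img, _ = generate_micrograph(p)
        with pytest.raises(BeadClippedError):
            fs.locate_bead(img)
        bead = fs.locate_bead(img, allow_clipped=True)
        assert bead.radius > 0


class TestLocateFollicle:
    def test_live_follicle_area_within_5pct(self):
        p = SyntheticParams(seed=6, follicle_radius=60.0, degradation_radius=155.0)
        img, _ = generate_micrograph(p)
        res = fs.analyze_micrograph(img)
        expected = math.pi * 60**2 * p.microns_per_pixel**2
        assert abs(res.follicle.area - expected) / expected <= 0.05

    def test_dead_phenotype_found_with_zero_degradation(self):
        img, _ = generate_micrograph(SyntheticParams(seed=8, degradation_radius=0.0))
        res = fs.analyze_micrograph(img)
        assert res.measurement.raw_area == 0.0
        assert res.measurement.corrected_area == 0.0
        # the darkest central blob is recovered at roughly the right size
        assert abs(res.follicle.equivalent_radius - 31) <= 5

    def test_seed_override_centers_on_seed(self, small_params):
        img, _ = generate_micrograph(small_params)
        bead = fs.locate_bead(img)
        mask = fs.binarize(img, fs.estimate_threshold(img, bead=bead))
        fol = fs.locate_follicle(img, mask, bead, seed_point=(128, 128))
        assert math.hypot(fol.center[0] - 128, fol.center[1] - 128) \
            <= small_params.follicle_radius

    def test_seed_on_degraded_pixel_raises(self, small_params):
        img, _ = generate_micrograph(small_params)
        bead = fs.locate_bead(img)
        mask = fs.binarize(img, fs.estimate_threshold(img, bead=bead))
        with pytest.raises(FollicleNotFoundError):
            # midway into the clearance: a degraded pixel
            fs.locate_follicle(img, mask, bead, seed_point=(128, 128 + 40))


class TestMeasureDegradation:
    def test_concentric_analytic_areas(self):
        """Analytic circle-area oracle: bead 400 px, clearance 150 px,
        follicle 50 px at 2 um/px."""
        p = SyntheticParams(
            image_size=(832, 832),
            bead_center=(416.0, 416.0),
            bead_radius=400.0,
            follicle_center=(416.0, 416.0),
            follicle_radius=50.0,
            degradation_radius=150.0,
            seed=13,
        )
        img, _ = generate_micrograph(p)
        res = fs.analyze_micrograph(img, allow_clipped_bead=True)
        m = res.measurement
        corrected_expect = math.pi * (150 * 2) ** 2
        raw_expect = math.pi * (150**2 - 50**2) * 4
        assert abs(m.corrected_area - corrected_expect) / corrected_expect <= 0.02
        assert abs(m.raw_area - raw_expect) / raw_expect <= 0.02
        assert not m.truncated

    def test_offset_clearance_near_edge_is_truncated(self):
        p = SyntheticParams(
            image_size=(832, 832),
            bead_center=(416.0, 416.0),
            bead_radius=400.0,
            follicle_center=(416.0, 416.0 + 380.0),
            follicle_radius=15.0,
            degradation_radius=150.0,
            seed=14,
        )
        img, truth = generate_micrograph(p)
        res = fs.analyze_micrograph(img, allow_clipped_bead=True)
        assert truth.truncated
        assert res.measurement.truncated

    def test_geometry_inconsistent_raises(self, small_params):
        img, _ = generate_micrograph(small_params)
        res = fs.analyze_micrograph(img)
        outside = fs.FollicleGeometry(center=(5.0, 5.0), equivalent_radius=10.0,
                                      area=100.0)
        with pytest.raises(GeometryError):
            fs.measure_degradation(res.mask, outside, res.bead)

    @pytest.mark.parametrize("r1, r2", [(60.0, 75.0), (75.0, 90.0)])
    def test_monotone_in_degradation_radius(self, small_params, r1, r2):
        a = fs.analyze_micrograph(
            generate_micrograph(replace(small_params, degradation_radius=r1))[0]
        ).measurement
        b = fs.analyze_micrograph(
            generate_micrograph(replace(small_params, degradation_radius=r2))[0]
        ).measurement
        assert a.corrected_area < b.corrected_area

    def test_compensation_identity_on_concentric_images(self, small_params):
        """Hole filling restores exactly the filled clearance disc."""
        img, truth = generate_micrograph(small_params)
        m = fs.analyze_micrograph(img).measurement
        assert m.corrected_area == pytest.approx(truth.degradation_area, rel=0.02)
        assert m.corrected_area >= m.raw_area

    def test_deterministic_bit_identical(self, small_params):
        img, _ = generate_micrograph(small_params)
        r1 = fs.analyze_micrograph(img)
        r2 = fs.analyze_micrograph(img)
        assert np.array_equal(r1.mask.degraded, r2.mask.degraded)
        assert r1.measurement == r2.measurement


class TestCheckTruncation:
    @pytest.mark.parametrize(
        "d, r_deg, r_bead, expected",
        [
            (0.0, 150.0, 400.0, False),  # 150 < 397
            (0.0, 399.0, 400.0, True),  # 399 >= 397
            (380.0, 150.0, 400.0, True),  # 530 >= 397
        ],
    )
    def test_analytic_predicate(self, d, r_deg, r_bead, expected):
        assert fs.circles_truncated(d, r_deg, r_bead, margin=3.0) is expected

    def test_pixel_component_against_predicate(self):
        bead = fs.BeadGeometry(center=(100.0, 100.0), radius=90.0)
        rr, cc = np.ogrid[:200, :200]
        near = np.hypot(rr - 100, cc - 100) <= 60  # well inside
        far = np.hypot(rr - 100, cc - 140) <= 55  # reaches 95 > 87
        assert not fs.check_truncation(near, bead, margin=3.0)
        assert fs.check_truncation(far, bead, margin=3.0)
        assert not fs.check_truncation(np.zeros((200, 200), bool), bead)
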