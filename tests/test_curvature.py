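"""Difference-curvature enhancement and orientation coding.

Oracles: analytic profiles (constant, linear, quadratic), symmetry
arguments (isotropic blob, 90-degree rotation), and a per-pixel
brute-force evaluation of the profile pipeline against the vectorized map.
"""

import numpy as np
import pytest

from veinmatch.curvature import (
    DIRECTION_ANGLES,
    binarize,
    curvature_differences,
    difference_curvature_map,
    directional_curvatures,
    orientation_encode,
    profile_curvature,
    sample_profile,
)
from veinmatch.phantom import PhantomSpec, generate_phantom, render_phantom
from veinmatch.preprocess import gaussian_smooth

from conftest import straight_vessel_lines


def smoothed_random(rng, shape=(40, 40)):
    return gaussian_smooth(rng.random(shape), 5, 3.0)


class TestSampleProfile:
    def test_constant_image(self):
        p = sample_profile(np.full((20, 20), 0.3), 10, 10, 0.7, r=4)
        assert p.shape == (9,)
        assert np.allclose(p, 0.3)

    def test_axis_aligned_reads_row(self, rng):
        img = rng.random((15, 15))
        p = sample_profile(img, 7, 7, 0.0, r=3)
        assert np.allclose(p, img[7, 4:11])

    def test_diagonal_on_bilinear_ramp(self):
        rows, cols = np.mgrid[0:21, 0:21]
        img = (rows + cols).astype(float)
        p = sample_profile(img, 10, 10, np.pi / 4, r=4)
        # along the 45-degree line the field grows by sqrt(2) per unit step
        steps = np.diff(p)
        assert np.allclose(steps, np.sqrt(2.0), atol=1e-9)

    def test_small_halfwidth_rejected(self):
        with pytest.raises(ValueError):
            sample_profile(np.zeros((9, 9)), 4, 4, 0.0, r=1)

    def test_out_of_bounds_center_rejected(self):
        with pytest.raises(ValueError):
            sample_profile(np.zeros((9, 9)), 12, 4, 0.0, r=2)


class TestProfileCurvature:
    @pytest.mark.parametrize("profile, expected", [
        (np.full(9, 3.7), 0.0),                       # flat
        (np.arange(-4.0, 5.0), 0.0),                  # linear, P'' = 0
        (np.arange(-2.0, 3.0) ** 2, 2.0),             # z^2: P''=2, P'=0
    ])
    def test_analytic_profiles(self, profile, expected):
        assert profile_curvature(profile) == pytest.approx(expected)

    def test_slope_reduces_curvature(self):
        z = np.arange(-2.0, 3.0)
        flat = profile_curvature(z**2)
        tilted = profile_curvature(z**2 + 3.0 * z)
        assert tilted < flat

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            profile_curvature(np.ones(4))
        with pytest.raises(ValueError):
            profile_curvature(np.array([1.0, 2.0, np.nan, 2.0, 1.0]))


class TestDifferenceCurvatureMap:
    def test_flat_image_zero_everywhere(self):
        assert np.allclose(difference_curvature_map(np.full((30, 30), 0.5)), 0.0)

    def test_nonnegative_on_random_images(self, rng):
        for _ in range(3):
            dmap = difference_curvature_map(smoothed_random(rng))
            assert dmap.min() >= 0.0

    def test_additive_offset_invariance(self, rng):
        img = smoothed_random(rng)
        assert np.allclose(difference_curvature_map(img),
                           difference_curvature_map(img + 0.37))

    def test_isotropic_blob_cancels_at_center(self):
        rows, cols = np.mgrid[0:41, 0:41]
        img = 0.8 - 0.3 * np.exp(-((rows - 20.0) ** 2 + (cols - 20.0) ** 2) / 18.0)
        dmap = difference_curvature_map(img)
        valley = 0.8 - 0.3 * np.exp(-((rows - 20.0) ** 2) / 18.0)
        dvalley = difference_curvature_map(valley)
        # orthogonal curvatures cancel on the blob but not on the valley
        assert dmap[20, 20] < 0.1 * dvalley[20, 20]

    def test_valley_centerline_is_global_maximum(self):
        rows, _ = np.mgrid[0:41, 0:61]
        img = 0.8 - 0.3 * np.exp(-((rows - 20.0) ** 2) / 18.0)
        dmap = difference_curvature_map(img)
        assert dmap[20, 30] > 0.0
        interior = dmap[:, 8:-8]
        assert interior.max() == pytest.approx(dmap[20, 30])
        assert np.argmax(interior.max(axis=1)) == 20

    def test_group_differences_are_antisymmetric(self, rng):
        k = directional_curvatures(smoothed_random(rng))
        dk = curvature_differences(k)
        assert np.allclose(dk[:4], -dk[4:])

    def test_matches_per_pixel_profile_oracle(self, rng):
        img = smoothed_random(rng, (15, 13))
        r = 4
        dmap = difference_curvature_map(img, r=r)
        for row in range(3, 12, 4):
            for col in range(3, 10, 3):
                ks = np.array([
                    profile_curvature(sample_profile(img, row, col, a, r=r))
                    for a in DIRECTION_ANGLES])
                expected = (ks - np.roll(ks, -4)).max()
                assert dmap[row, col] == pytest.approx(expected, abs=1e-12)

    def test_quarter_rotation_equivariance(self, rng):
        img = smoothed_random(rng)
        a = difference_curvature_map(np.rot90(img))
        b = np.rot90(difference_curvature_map(img))
        assert np.allclose(a[6:-6, 6:-6], b[6:-6, 6:-6], atol=1e-10)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            difference_curvature_map(np.zeros((7, 30)), r=4)


class TestBinarize:
    def test_zero_map_any_positive_threshold(self):
        assert not binarize(np.zeros((5, 5)), 0.1).any()

    def test_threshold_zero_marks_positives(self):
        dmap = np.zeros((4, 4))
        dmap[1, 2] = 0.5
        mask = binarize(dmap, 0.0)
        assert mask[1, 2] == 1 and mask.sum() == 1

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((4, 4)), -0.5)

    def test_automatic_threshold_segments_single_vessel(self):
        spec = PhantomSpec(n_vessels=1, seed=2)
        ph = render_phantom(spec, straight_vessel_lines())
        dmap = difference_curvature_map(gaussian_smooth(ph.image))
        mask = binarize(dmap).astype(bool)
        truth = ph.vessel_mask.astype(bool)
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.7

    def test_otsu_rule_gives_plausible_band(self):
        spec = PhantomSpec(n_vessels=1, seed=2)
        ph = render_phantom(spec, straight_vessel_lines())
        dmap = difference_curvature_map(gaussian_smooth(ph.image))
        mask = binarize(dmap, "otsu").astype(bool)
        truth = ph.vessel_mask.astype(bool)
        # between-class-variance threshold admits more shoulder pixels than
        # the entropy rule but still recovers most of the vessel band
        recall = (mask & truth).sum() / truth.sum()
        assert recall >= 0.8


class TestOrientationEncode:
    def test_flat_region_tie_breaks_to_code_one(self):
        img = np.full((20, 20), 0.5)
        support = np.ones_like(img, dtype=np.uint8)
        codes = orientation_encode(img, support=support)
        assert np.all(codes == 1)

    def test_background_coded_zero(self, rng):
        img = smoothed_random(rng, (20, 20))
        support = np.zeros((20, 20), dtype=np.uint8)
        support[5:8, 5:8] = 1
        codes = orientation_encode(img, support=support)
        assert np.all(codes[support == 0] == 0)
        assert np.all(codes[support == 1] >= 1)

    def test_vertical_stripe_codes_horizontal_cross_section(self):
        _, cols = np.mgrid[0:41, 0:41]
        img = 0.8 - 0.3 * np.exp(-((cols - 20.0) ** 2) / 18.0)
        codes = orientation_encode(img)
        # cross-section of a vertical stripe is the theta=0 direction
        assert np.all(codes[10:30, 20] == 1)

    def test_quarter_rotation_shifts_codes_by_four(self, rng):
        img = smoothed_random(rng)
        a = orientation_encode(np.rot90(img))
        b = np.rot90(orientation_encode(img))
        expected = ((b.astype(int) - 1 + 4) % 8) + 1
        inner = np.s_[8:-8, 8:-8]
        match = (a[inner] == expected[inner]).mean()
        assert match > 0.95  # near-tie pixels may flip groups

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            orientation_encode(np.zeros((10, 10)), support=np.zeros((5, 5)))

    def test_codes_perpendicular_to_tangent_on_clean_phantom(self):
        from scipy.ndimage import binary_erosion
        spec = PhantomSpec(noise_sd=0.0, seed=4)
        ph = generate_phantom(spec)
        img = gaussian_smooth(ph.image)
        dmap = difference_curvature_map(img)
        codes = orientation_encode(img, support=ph.vessel_mask.astype(np.uint8))
        interior = binary_erosion(ph.vessel_mask.astype(bool), iterations=2)
        code_angle = (codes[interior].astype(float) - 1.0) * np.pi / 8
        perp = np.mod(ph.tangent_angle[interior] + np.pi / 2, np.pi)
        # circular distance on the half-turn circle, within one code step
        delta = np.abs(code_angle - perp)
        delta = np.minimum(delta, np.pi - delta)
        assert (delta <= np.pi / 8 + 1e-9).mean() >= 0.9
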