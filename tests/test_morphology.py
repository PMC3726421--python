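import numpy as np
import pytest

import oracles
from nucseg.morphology import (
    extended_regional_minima,
    h_minima_transform,
    label_minima,
    preprocess_at_scale,
    reconstruct_close,
    reconstruct_open,
    regional_minima,
    skeletonize,
)


def random_blocky_image(rng, shape=(40, 40), levels=8):
    """Piecewise-flat random image: realistic plateaus for minima tests."""
    from scipy import ndimage as ndi

    img = rng.integers(0, levels, shape).astype(float)
    return ndi.grey_closing(img, size=2)


class TestReconstructionFilters:
    def test_flat_image_is_fixed_point(self):
        img = np.full((20, 20), 7.0)
        assert np.array_equal(reconstruct_open(img, 3), img)
        assert np.array_equal(reconstruct_close(img, 3), img)

    def test_small_bright_square_removed_by_opening(self):
        img = np.zeros((40, 40))
        img[10:14, 10:14] = 100.0  # side 4 < disk(5)
        out = reconstruct_open(img, 5)
        assert np.array_equal(out, oracles.reconstruction_by_dilation(
            _eroded(img, 5), img))
        assert out.max() == 0.0

    def test_large_bright_plateau_preserved_by_opening(self):
        img = np.zeros((40, 40))
        img[5:35, 5:35] = 100.0
        out = reconstruct_open(img, 5)
        assert np.array_equal(out, img)

    def test_small_dark_speckle_removed_by_closing(self):
        img = np.full((40, 40), 200.0)
        img[20:22, 20:22] = 10.0
        out = reconstruct_close(img, 4)
        assert out.min() == 200.0

    def test_large_dark_blob_preserved_by_closing(self):
        img = np.full((40, 40), 200.0)
        img[5:35, 5:35] = 10.0
        assert np.array_equal(reconstruct_close(img, 4), img)

    def test_ordering_and_idempotence(self):
        rng = np.random.default_rng(3)
        img = random_blocky_image(rng)
        op = reconstruct_open(img, 3)
        cl = reconstruct_close(img, 3)
        assert np.all(op <= img) and np.all(cl >= img)
        assert np.array_equal(reconstruct_open(op, 3), op)
        assert np.array_equal(reconstruct_close(cl, 3), cl)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            reconstruct_open(np.zeros((20, 20)), 15)

    def test_matches_bruteforce_oracle_on_random_images(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            img = random_blocky_image(rng, (24, 24))
            assert np.array_equal(
                reconstruct_open(img, 2),
                oracles.reconstruction_by_dilation(_eroded(img, 2), img),
            )
            assert np.array_equal(
                reconstruct_close(img, 2),
                oracles.reconstruction_by_erosion(_dilated(img, 2), img),
            )


def _eroded(img, r):
    from scipy import ndimage as ndi
    from nucseg.morphology import disk_footprint

    return ndi.grey_erosion(img, footprint=disk_footprint(r), mode="nearest")


def _dilated(img, r):
    from scipy import ndimage as ndi
    from nucseg.morphology import disk_footprint

    return ndi.grey_dilation(img, footprint=disk_footprint(r), mode="nearest")


class TestHMinima:
    def test_zero_depth_is_identity(self):
        rng = np.random.default_rng(1)
        img = random_blocky_image(rng)
        assert np.array_equal(h_minima_transform(img, 0.0), img)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            h_minima_transform(np.zeros((4, 4)), -0.1)

    def test_only_deep_basin_survives(self):
        # 1-D-style profile: basins of depth 0.3 and 0.5, threshold 0.4
        profile = np.array([1.0, 0.7, 1.0, 0.5, 1.0])
        img = np.tile(profile, (5, 1))
        mask = extended_regional_minima(img, 0.4)
        _, count = label_minima(mask)
        assert count == 1
        assert mask[2, 3] and not mask[2, 1]

    def test_bounded_increase_property(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            img = random_blocky_image(rng, (20, 20))
            h = float(rng.uniform(0.1, 3.0))
            out = h_minima_transform(img, h)
            assert np.all(out >= img)
            assert np.all(out - img <= h + 1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            img = random_blocky_image(rng, (20, 20))
            h = float(rng.integers(1, 4))
            assert np.array_equal(h_minima_transform(img, h), oracles.h_minima(img, h))


class TestRegionalMinima:
    def test_monotone_ramp_has_single_low_edge_component(self):
        ramp = np.tile(np.arange(8.0), (5, 1))
        mask = regional_minima(ramp)
        _, count = label_minima(mask)
        assert count == 1 and mask[:, 0].all() and not mask[:, 1:].any()

    def test_constant_image_is_one_full_frame_minimum(self):
        mask = regional_minima(np.full((6, 6), 2.0))
        assert mask.all()

    def test_shift_invariance_of_extended_minima(self):
        rng = np.random.default_rng(2)
        img = random_blocky_image(rng)
        assert np.array_equal(
            extended_regional_minima(img, 1.5),
            extended_regional_minima(img + 11.0, 1.5),
        )

    def test_extended_equals_minima_of_h_transform(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            img = random_blocky_image(rng, (24, 24))
            assert np.array_equal(
                extended_regional_minima(img, 2.0),
                regional_minima(h_minima_transform(img, 2.0)),
            )

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            img = random_blocky_image(rng, (18, 18))
            assert np.array_equal(regional_minima(img), oracles.regional_minima(img))


class TestPreprocess:
    def test_flat_image_unchanged_and_tagged(self):
        out = preprocess_at_scale(np.full((64, 64), 128.0), 10)
        assert out.scale == 10
        assert np.array_equal(out.pixels, np.full((64, 64), 128.0))

    def test_interior_speckles_flattened(self):
        # dark nucleus with small bright interior speckles at scale 10
        img = np.full((80, 80), 220.0)
        yy, xx = np.mgrid[:80, :80]
        disk = (yy - 40) ** 2 + (xx - 40) ** 2 <= 25**2
        img[disk] = 60.0
        rng = np.random.default_rng(0)
        for _ in range(6):  # speckles of diameter ~4 < 10
            cy, cx = rng.integers(30, 50, 2)
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 2**2] = 160.0
        out = preprocess_at_scale(img, 10).pixels
        interior = (yy - 40) ** 2 + (xx - 40) ** 2 <= 15**2
        assert out[interior].max() - out[interior].min() < 5

    def test_thin_dark_protrusion_removed(self):
        img = np.full((80, 80), 220.0)
        yy, xx = np.mgrid[:80, :80]
        disk = (yy - 40) ** 2 + (xx - 30) ** 2 <= 15**2
        img[disk] = 60.0
        img[39:42, 45:70] = 60.0  # 3-px-wide dark tail, width < n/2
        out = preprocess_at_scale(img, 10).pixels
        assert out[40, 60] > 150.0

    def test_rejects_tiny_scale(self):
        with pytest.raises(ValueError):
            preprocess_at_scale(np.zeros((32, 32)), 1)


class TestSkeletonize:
    def test_skeleton_subset_and_empty_cases(self):
        assert not skeletonize(np.zeros((10, 10), bool)).any()
        mask = np.zeros((40, 40), bool)
        mask[:] = True
        mask[18:22, 18:22] = False  # frame with a hole
        skel = skeletonize(mask)
        assert skel.any()
        assert not skel[~mask].any()

    def test_one_pixel_line_is_fixed_point(self):
        line = np.zeros((9, 9), bool)
        line[4, 1:8] = True
        assert np.array_equal(skeletonize(line), line)

    def test_connectivity_preserved_around_hole(self):
        from scipy import ndimage as ndi

        mask = np.ones((50, 50), bool)
        yy, xx = np.mgrid[:50, :50]
        mask[(yy - 25) ** 2 + (xx - 25) ** 2 <= 8**2] = False
        skel = skeletonize(mask)
        _, n = ndi.label(skel, structure=np.ones((3, 3), bool))
        assert n == 1  # closed curve system around the hole stays connected
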