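import numpy as np
import pytest
from scipy import ndimage as ndi

from nucseg.frst import SymmetryMap, frst_orientation_only
from nucseg.morphology import PreprocessedImage, preprocess_at_scale
from nucseg.watershed import (
    MarkerSet,
    MarkersTooDenseError,
    build_background_marker,
    extract_frst_markers,
    extract_minima_markers,
    impose_minima,
    watershed_with_markers,
)


def two_disk_image(shape=(128, 128), centers=((40, 40), (88, 88)), radius=14):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.full(shape, 220.0)
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = 60.0
    return img


class TestFrstMarkers:
    def test_constant_map_yields_no_markers(self):
        sym = SymmetryMap(np.zeros((32, 32)), np.zeros((32, 32)), (5,))
        assert extract_frst_markers(sym).max() == 0

    def test_single_deep_basin_yields_one_marker(self):
        yy, xx = np.mgrid[:40, :40]
        raw = ((yy - 20) ** 2 + (xx - 20) ** 2) / 400.0  # parabolic basin
        norm = (raw - raw.min()) / (raw.max() - raw.min())
        sym = SymmetryMap(raw, norm, (5,))
        labels = extract_frst_markers(sym, h=0.4)
        assert labels.max() == 1

    def test_two_disks_fixture_yields_two_markers(self):
        img = two_disk_image()
        pre = preprocess_at_scale(img, 10)
        sym = frst_orientation_only(pre.pixels, range(10, 21))
        labels = extract_frst_markers(sym, h=0.4)
        assert labels.max() == 2


class TestMinimaMarkers:
    def test_two_dark_disks_give_two_markers(self):
        pre = preprocess_at_scale(two_disk_image(), 10)
        labels = extract_minima_markers(pre)
        assert labels.max() == 2

    def test_uniform_image_gives_no_markers(self):
        pre = PreprocessedImage(np.full((64, 64), 100.0), 10)
        assert extract_minima_markers(pre).max() == 0

    def test_single_disk_gives_one_marker(self):
        pre = preprocess_at_scale(two_disk_image(centers=((64, 64),)), 10)
        assert extract_minima_markers(pre).max() == 1


class TestBackgroundMarker:
    def test_requires_markers(self):
        with pytest.raises(ValueError):
            build_background_marker(np.zeros((32, 32), int), 5)

    def test_skeleton_disjoint_from_dilated_marker(self):
        fg = np.zeros((128, 128), int)
        fg[60:64, 60:64] = 1
        skel = build_background_marker(fg, 10)
        assert skel.any()
        dil = ndi.distance_transform_edt(fg == 0) <= 20
        assert not (skel & dil).any()

    def test_dense_markers_raise(self):
        fg = np.zeros((40, 40), int)
        fg[18:22, 18:22] = 1
        with pytest.raises(MarkersTooDenseError):
            build_background_marker(fg, 15)

    def test_skeleton_separates_two_distant_markers(self):
        fg = np.zeros((200, 200), int)
        fg[50, 50] = 1
        fg[150, 150] = 2
        skel = build_background_marker(fg, 10)
        # flood from marker 1 through non-skeleton pixels: marker 2 must be
        # unreachable without crossing the skeleton (4-connectivity for the
        # complement, the dual of the 8-connected thin skeleton)
        open_space, _ = ndi.label(~skel)
        assert open_space[50, 50] != open_space[150, 150]


class TestImposeMinima:
    def test_minima_appear_exactly_at_markers(self):
        from nucseg.morphology import regional_minima

        rng = np.random.default_rng(0)
        img = ndi.gaussian_filter(rng.random((48, 48)), 2)
        mask = np.zeros((48, 48), bool)
        mask[10:12, 10:12] = True
        mask[30:32, 35:37] = True
        out = impose_minima(img, mask)
        minima = regional_minima(out)
        labels, n = ndi.label(minima, structure=np.ones((3, 3), bool))
        assert n == 2
        assert minima[mask].all()


class TestWatershed:
    def _segment_two_disks(self, centers=((40, 40), (88, 88)), radius=14):
        img = two_disk_image(centers=centers, radius=radius)
        pre = preprocess_at_scale(img, 10)
        fg = extract_minima_markers(pre)
        bg = build_background_marker(fg, 10)
        markers = MarkerSet(fg, bg, "minima", 10)
        return img, markers, watershed_with_markers(pre, markers)

    def test_one_region_per_marker_and_containment(self):
        _, markers, result = self._segment_two_disks()
        assert result.n_regions == markers.n_markers == 2
        for lab in (1, 2):
            marker_px = markers.foreground == lab
            assert (result.labels[marker_px] == result.labels[marker_px][0]).all()
            assert result.labels[marker_px][0] > 0

    def test_region_recovers_most_of_disk(self):
        img, _, result = self._segment_two_disks(centers=((64, 64),), radius=14)
        disk = img == 60.0
        region = result.labels == result.labels[64, 64]
        assert (region & disk).sum() >= 0.8 * disk.sum()

    def test_touching_disks_split_near_tangent_chord(self):
        # two disks touching along x: the shared watershed boundary must
        # stay within 2 px of the vertical tangent chord
        img = two_disk_image(centers=((64, 50), (64, 78)), radius=14)
        pre = preprocess_at_scale(img, 10)
        fg = np.zeros(img.shape, int)
        fg[64, 50] = 1
        fg[64, 78] = 2
        bg = build_background_marker(fg, 10)
        result = watershed_with_markers(pre, MarkerSet(fg, bg, "minima", 10))
        assert result.n_regions == 2
        both = (result.labels == 1) | (result.labels == 2)
        boundary_cols = []
        for r in range(img.shape[0]):
            cols = np.nonzero(result.labels[r] == 1)[0]
            cols2 = np.nonzero(result.labels[r] == 2)[0]
            if cols.size and cols2.size:
                boundary_cols.append((cols.max() + cols2.min()) / 2)
        assert both.any() and boundary_cols
        assert np.all(np.abs(np.array(boundary_cols) - 64.0) <= 2.0)

    def test_region_count_equals_marker_count_fuzzed(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            img = ndi.gaussian_filter(rng.random((96, 96)) * 255, 3)
            pre = PreprocessedImage(img, 8)
            k = int(rng.integers(1, 6))
            fg = np.zeros(img.shape, int)
            for lab in range(1, k + 1):
                while True:
                    r, c = rng.integers(8, 88, 2)
                    if not fg[max(r - 3, 0) : r + 4, max(c - 3, 0) : c + 4].any():
                        fg[r : r + 2, c : c + 2] = lab
                        break
            try:
                bg = build_background_marker(fg, 4)
            except MarkersTooDenseError:
                continue
            result = watershed_with_markers(pre, MarkerSet(fg, bg, "minima", 8))
            assert result.n_regions == k
            for lab in range(1, k + 1):
                vals = result.labels[fg == lab]
                assert (vals == vals[0]).all() and vals[0] > 0
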