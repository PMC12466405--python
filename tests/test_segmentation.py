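import numpy as np
import pytest

from netquant import (
    ROISpec,
    compute_fi_threshold,
    measure_nuclei,
    segment_nuclei,
    split_touching_nuclei,
)
from netquant.errors import DegenerateHistogramError

from _oracles import flood_fill_label, otsu_exhaustive, same_partition


class TestFIThreshold:
    def test_manual_passthrough(self, mk_image):
        img = mk_image(np.zeros((4, 4)))
        assert compute_fi_threshold(img, "manual", 500) == 500.0

    def test_manual_out_of_range(self, mk_image):
        img = mk_image(np.zeros((4, 4)), bit_depth=8)
        with pytest.raises(ValueError):
            compute_fi_threshold(img, "manual", 300)

    def test_otsu_two_level_against_exhaustive_sweep(self, mk_image):
        arr = np.full((10, 10), 10, dtype=np.uint16)
        arr[5:] = 200
        img = mk_image(arr)
        t = compute_fi_threshold(img, "otsu")
        assert 10 <= t < 200
        oracle = otsu_exhaustive(arr)
        # both cuts must induce the same foreground
        np.testing.assert_array_equal(arr > t, arr > oracle)

    def test_otsu_constant_image_degenerate(self, mk_image):
        with pytest.raises(DegenerateHistogramError):
            compute_fi_threshold(mk_image(np.zeros((8, 8))), "otsu")


class TestSegmentation:
    def test_two_disjoint_squares(self, mk_image):
        arr = np.zeros((10, 10), dtype=np.uint16)
        arr[1:4, 1:4] = 100
        arr[6:9, 6:9] = 100
        lm = segment_nuclei(mk_image(arr), threshold=50)
        assert lm.n_objects == 2
        assert (lm.labels == 1).sum() == 9
        assert (lm.labels == 2).sum() == 9

    def test_empty_when_nothing_above_threshold(self, mk_image):
        lm = segment_nuclei(mk_image(np.zeros((5, 5))), threshold=0)
        assert lm.n_objects == 0

    def test_strict_inequality_at_threshold(self, mk_image):
        arr = np.full((3, 3), 50, dtype=np.uint16)
        assert segment_nuclei(mk_image(arr), threshold=50).n_objects == 0
        assert segment_nuclei(mk_image(arr), threshold=49).n_objects == 1

    def test_labels_follow_raster_order(self, mk_image):
        arr = np.zeros((5, 5), dtype=np.uint16)
        arr[3, 0] = 100  # later in raster order
        arr[0, 4] = 100  # first foreground pixel encountered
        lm = segment_nuclei(mk_image(arr), threshold=50)
        assert lm.labels[0, 4] == 1
        assert lm.labels[3, 0] == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_on_random_grids(self, mk_image, connectivity):
        rng = np.random.default_rng(11)
        for _ in range(50):
            binary = rng.random((16, 16)) < 0.45
            img = mk_image(binary.astype(np.uint16) * 100)
            lm = segment_nuclei(img, threshold=50, connectivity=connectivity)
            oracle = flood_fill_label(binary, connectivity)
            assert same_partition(lm.labels, oracle)
            assert lm.n_objects == oracle.max()

    def test_threshold_sweep_monotone_foreground(self, mk_image):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 1000, size=(32, 32), dtype=np.uint16)
        img = mk_image(arr)
        previous = arr.size + 1
        for t in range(0, 1000, 50):
            fg = (segment_nuclei(img, t).labels > 0).sum()
            assert fg <= previous
            previous = fg


def _disc_mask(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestSplitting:
    def test_single_disc_unchanged(self, mk_image):
        mask = _disc_mask((20, 20), (10, 10), 6)
        img = mk_image(mask.astype(np.uint16) * 100)
        lm = segment_nuclei(img, 50)
        out = split_touching_nuclei(lm, img, min_peak_separation_um=3.0)
        assert out.n_objects == 1
        np.testing.assert_array_equal(out.labels > 0, lm.labels > 0)

    def test_two_overlapping_discs_split(self, mk_image):
        mask = _disc_mask((30, 30), (15, 10), 6) | _disc_mask((30, 30), (15, 20), 6)
        img = mk_image(mask.astype(np.uint16) * 100)
        lm = segment_nuclei(img, 50)
        assert lm.n_objects == 1  # merged clump
        out = split_touching_nuclei(lm, img, min_peak_separation_um=5.0)
        assert out.n_objects == 2
        sizes = sorted((out.labels == k).sum() for k in (1, 2))
        assert sizes[1] - sizes[0] <= 0.1 * sizes[1]

    def test_infinite_separation_disables_stage(self, mk_image):
        mask = _disc_mask((30, 30), (15, 10), 6) | _disc_mask((30, 30), (15, 20), 6)
        img = mk_image(mask.astype(np.uint16) * 100)
        lm = segment_nuclei(img, 50)
        out = split_touching_nuclei(lm, img, min_peak_separation_um=np.inf)
        np.testing.assert_array_equal(out.labels, lm.labels)

    def test_object_count_never_decreases(self, mk_image):
        rng = np.random.default_rng(3)
        binary = rng.random((40, 40)) < 0.3
        img = mk_image(binary.astype(np.uint16) * 100)
        lm = segment_nuclei(img, 50)
        out = split_touching_nuclei(lm, img, min_peak_separation_um=2.0)
        assert out.n_objects >= lm.n_objects
        # splitting re-partitions the same foreground
        np.testing.assert_array_equal(out.labels > 0, lm.labels > 0)


class TestMeasurement:
    def test_uniform_square(self, mk_image):
        arr = np.zeros((8, 8), dtype=np.uint16)
        arr[2:5, 2:5] = 120
        img = mk_image(arr, pixel_size_um=1.0)
        lm = segment_nuclei(img, 50)
        (rec,) = measure_nuclei(lm, img)
        assert rec.area_px == 9
        assert rec.area_um2 == pytest.approx(9.0)
        assert rec.mean_fi == pytest.approx(120.0)
        assert not rec.touches_roi_border

    def test_border_contact_flag(self, mk_image):
        arr = np.zeros((6, 6), dtype=np.uint16)
        arr[0:2, 2:4] = 90  # spans the first row
        img = mk_image(arr)
        lm = segment_nuclei(img, 50)
        (rec,) = measure_nuclei(lm, img)
        assert rec.touches_roi_border

    def test_empty_labelmap_gives_empty_list(self, mk_image):
        img = mk_image(np.zeros((5, 5)))
        lm = segment_nuclei(img, 0)
        assert measure_nuclei(lm, img) == []

    def test_mean_fi_matches_brute_force(self, mk_image):
        rng = np.random.default_rng(17)
        for _ in range(50):
            arr = rng.integers(0, 4000, size=(24, 24), dtype=np.uint16)
            binary = rng.random((24, 24)) < 0.4
            img = mk_image(np.where(binary, arr, 0))
            lm = segment_nuclei(img, 0)
            for rec in measure_nuclei(lm, img):
                pix = img.pixels[lm.labels == rec.label]
                assert rec.mean_fi == pytest.approx(pix.sum() / pix.size, rel=1e-9)
                assert rec.area_px == pix.size

    def test_centroid_respects_roi_offset(self, mk_image):
        arr = np.zeros((10, 10), dtype=np.uint16)
        arr[4:6, 4:6] = 100
        img = mk_image(arr, pixel_size_um=2.0)
        roi = ROISpec(x0_um=100.0, y0_um=40.0, width_um=20.0, height_um=20.0, index=3)
        lm = segment_nuclei(img, 50)
        (rec,) = measure_nuclei(lm, img, roi)
        assert rec.roi_index == 3
        assert rec.centroid_um[0] == pytest.approx(100.0 + 10.0)
        assert rec.centroid_um[1] == pytest.approx(40.0 + 10.0)

    def test_object_area_sum_bounded_by_foreground(self, mk_image):
        rng = np.random.default_rng(29)
        arr = rng.integers(0, 300, size=(32, 32), dtype=np.uint16)
        img = mk_image(arr)
        lm = segment_nuclei(img, 150)
        fg = int((arr > 150).sum())
        assert sum(r.area_px for r in measure_nuclei(lm, img)) == fg
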