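"""Morphometry: top-hat, binarization, skeletonization, branch points, densities."""

import numpy as np
import pytest
from skimage import morphology as skmorph

from mtnet import morphometry as mm, synth
from mtnet.morphometry import (
    CellMask,
    EmptyFieldError,
    FilamentImage,
    binarize,
    detect_branchpoints,
    detect_cell_area,
    enhance_tophat,
    measure,
    prune_spurs,
    skeletonize,
)


def _img(arr, **kw):
    return FilamentImage(np.asarray(arr, dtype=float), **kw)


class TestTophat:
    def test_constant_image_maps_to_zero(self):
        out = enhance_tophat(_img(np.full((32, 32), 7.0)), radius_px=5)
        assert np.allclose(out.pixels, 0.0)

    def test_thin_line_preserved(self):
        arr = np.zeros((32, 32))
        arr[16, 4:28] = 10.0
        out = enhance_tophat(_img(arr), radius_px=5)
        assert np.all(out.pixels[16, 6:26] > 0)
        off = out.pixels.copy()
        off[16, :] = 0
        assert np.allclose(off, 0.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_output_bounded_by_input_and_nonnegative(self, seed):
        arr = np.random.default_rng(seed).uniform(0, 100, size=(48, 48))
        out = enhance_tophat(_img(arr), radius_px=4)
        assert np.all(out.pixels >= 0)
        assert np.all(out.pixels <= arr + 1e-9)

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            enhance_tophat(_img(np.zeros((8, 8))), radius_px=0)


class TestBinarize:
    def test_strictly_above_threshold(self):
        mask = binarize(_img([[0.2, 0.8]]), 0.5)
        assert mask.tolist() == [[False, True]]

    def test_extreme_thresholds(self):
        img = _img(np.arange(9.0).reshape(3, 3))
        assert binarize(img, -1.0).all()
        assert not binarize(img, 9.0).any()

    def test_nan_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(_img(np.zeros((4, 4))), float("nan"))


class TestSkeletonize:
    def test_thin_line_is_fixed_point(self):
        m = np.zeros((16, 16), dtype=bool)
        m[8, 2:14] = True
        assert np.array_equal(skeletonize(m), m)

    def test_empty_mask(self):
        assert not skeletonize(np.zeros((8, 8), dtype=bool)).any()

    def test_rectangle_matches_thinning_oracle(self):
        # independent oracle: Guo-Hall thinning (a different thinning scheme);
        # algorithms may keep or drop one endpoint pixel, hence the 1-px slack
        m = np.zeros((7, 13), dtype=bool)
        m[2:5, 2:11] = True  # 9x3 filled rectangle
        skel = skeletonize(m)
        oracle = skmorph.thin(m)
        assert abs(int(skel.sum()) - int(oracle.sum())) <= 1
        from scipy import ndimage as ndi

        _, n_comp = ndi.label(skel, structure=np.ones((3, 3), int))
        assert n_comp == 1  # a single connected medial line
        assert detect_branchpoints(skel)[0] == 0
        assert skel[3, 3:9].all()  # medial row core present

    @pytest.mark.parametrize("seed", range(4))
    def test_idempotence_on_random_masks(self, seed):
        m = np.random.default_rng(seed).random((60, 60)) > 0.55
        s1 = skeletonize(m)
        assert np.array_equal(skeletonize(s1), s1)
        assert not (s1 & ~m).any()  # skeleton is a subset of the mask


class TestBranchpoints:
    def test_plus_cross_counts_one(self):
        m = np.zeros((11, 11), dtype=bool)
        m[5, 1:10] = True
        m[1:10, 5] = True
        count, _ = detect_branchpoints(m)
        assert count == 1

    def test_straight_line_counts_zero(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 1:8] = True
        assert detect_branchpoints(m)[0] == 0

    def test_y_junction_counts_one(self):
        m = np.zeros((11, 11), dtype=bool)
        m[5, 5] = True
        m[4, 5] = m[3, 5] = m[2, 5] = True  # up
        m[6, 4] = m[7, 3] = m[8, 2] = True  # down-left
        m[6, 6] = m[7, 7] = m[8, 8] = True  # down-right
        assert detect_branchpoints(m)[0] == 1

    def test_spur_pruning_removes_twig_keeps_filaments(self):
        m = np.zeros((21, 21), dtype=bool)
        m[10, 1:20] = True  # long filament
        m[7, 10] = m[8, 10] = m[9, 10] = True  # 3-px twig off it
        assert detect_branchpoints(m)[0] == 1
        pruned = prune_spurs(m, min_length=5)
        assert detect_branchpoints(pruned)[0] == 0
        assert pruned[10, 1:20].all()


class TestMeasure:
    def test_density_arithmetic(self):
        mask = CellMask(np.ones((50, 40), dtype=bool))  # area 2000
        skel = np.zeros((50, 40), dtype=bool)
        skel[:25, :20] = True  # 500 px
        res = measure(mask, skel, branchpoint_count=5)
        assert res.mt_density == pytest.approx(0.25)
        assert res.crossing_density == pytest.approx(5 / 500.0)

    def test_empty_skeleton_flags_crossing_density(self):
        mask = CellMask(np.ones((40, 50), dtype=bool))
        res = measure(mask, np.zeros((40, 50), dtype=bool), 0)
        assert res.mt_density == 0.0
        assert not res.crossing_density_defined
        assert np.isnan(res.crossing_density)

    def test_diagonal_weighting(self):
        skel = np.eye(10, dtype=bool)
        plain = mm.skeleton_length(skel)
        weighted = mm.skeleton_length(skel, diagonal_weighting=True)
        assert plain == 10
        assert weighted == pytest.approx(9 * np.sqrt(2.0))


class TestCellArea:
    def test_disk_of_filaments_recovered(self):
        spec = synth.NetworkSpec(n_filaments=150, seed=1, noise_sd=5.0)
        img, _ = synth.generate_filament_image(spec)
        h, w = img.shape
        yy, xx = np.mgrid[:h, :w]
        radius = 180
        disk = (yy - h / 2) ** 2 + (xx - w / 2) ** 2 <= radius**2
        arr = np.where(disk, img.pixels, spec.background_level)
        cell = detect_cell_area(_img(arr))
        assert cell.area == pytest.approx(disk.sum(), rel=0.10)

    def test_all_zero_image_raises(self):
        with pytest.raises(EmptyFieldError):
            detect_cell_area(_img(np.zeros((128, 128))))

    def test_saturated_image_covers_frame(self):
        cell = detect_cell_area(_img(np.full((64, 64), 65535.0)))
        assert cell.area == 64 * 64


class TestOnSyntheticNetworks:
    def test_translation_invariance(self, parallel_network):
        img, _ = parallel_network
        arr = img.pixels
        shifted = np.roll(arr, (7, -11), axis=(0, 1))

        def metrics(a):
            b = binarize(enhance_tophat(_img(a), 5), 200.0)
            sk = prune_spurs(skeletonize(b), 10)
            return int(sk.sum()), detect_branchpoints(sk)[0]

        # roll wraps content; tolerate the few pixels cut at the frame edge
        len0, br0 = metrics(arr)
        len1, br1 = metrics(shifted)
        assert abs(len1 - len0) <= 0.02 * len0
        assert abs(br1 - br0) <= 2

    def test_parallel_network_ground_truth(self, parallel_network):
        img, truth = parallel_network
        b = binarize(enhance_tophat(img, 5), 200.0)
        skel = prune_spurs(skeletonize(b), 10)
        assert detect_branchpoints(skel)[0] == 0
        assert skel.sum() == pytest.approx(truth.centerline_length, rel=0.15)

    def test_crossing_detection_monotone_in_filaments(self):
        counts = []
        for n in (6, 8, 10, 12):
            spec = synth.NetworkSpec(n_filaments=n, seed=7, noise_seed=1)
            img, _ = synth.generate_filament_image(spec)
            b = binarize(enhance_tophat(img, 5), 200.0)
            skel = prune_spurs(skeletonize(b), 10)
            counts.append(detect_branchpoints(skel)[0])
        assert all(b >= a for a, b in zip(counts, counts[1:]))
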