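import numpy as np
import pytest

import palmvein as pv
from palmvein.features import Keypoint, MatchPair
from palmvein.mismatch_removal import (FilteredMatches, HistogramDistance,
                                       LBPFilterConfig, MatchLabel,
                                       NeighborFilterConfig, _transitions)
from palmvein.preprocess import finalize_mask


def square_mask(shape, top, left, size):
    bits = np.zeros(shape, dtype=bool)
    bits[top:top + size, left:left + size] = True
    return finalize_mask(bits)


def pair_list(n):
    return [MatchPair(i, i, 0.1, 0.5) for i in range(n)]


class TestLbpCode:
    def test_constant_patch_codes_255(self):
        assert pv.lbp_code(np.full((3, 3), 9)) == 255

    def test_hand_computed_example(self):
        # center 6; clockwise from top-left 6,7,8,5,4,3,2,9 -> bits 11100001
        patch = np.array([[6, 7, 8],
                          [9, 6, 5],
                          [2, 3, 4]])
        assert pv.lbp_code(patch) == 135

    def test_bright_center_codes_zero(self):
        patch = np.zeros((3, 3))
        patch[1, 1] = 255
        assert pv.lbp_code(patch) == 0

    def test_uniform_pattern_count_is_58(self):
        assert sum(1 for c in range(256) if _transitions(c) <= 2) == 58


class TestUniformLbpHistogram:
    def test_constant_window_single_bin(self):
        img = np.full((64, 64), 40, dtype=np.uint8)
        cfg = LBPFilterConfig(patch_size=16)
        h = pv.uniform_lbp_histogram(img, Keypoint(32, 32, 1, 0), cfg)
        assert h.sum() == (16 - 2) ** 2
        assert h.max() == (16 - 2) ** 2  # all codes 255, a uniform pattern

    def test_mass_conservation(self, rng):
        img = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        cfg = LBPFilterConfig(patch_size=20)
        h = pv.uniform_lbp_histogram(img, Keypoint(30, 30, 1, 0), cfg)
        assert h.sum() == (20 - 2) ** 2
        assert h.shape == (59,)

    def test_additive_offset_invariance(self, rng):
        img = rng.integers(40, 160, size=(64, 64)).astype(np.uint8)
        cfg = LBPFilterConfig(patch_size=16)
        kp = Keypoint(32, 32, 1, 0)
        h1 = pv.uniform_lbp_histogram(img, kp, cfg)
        h2 = pv.uniform_lbp_histogram(img + 40, kp, cfg)  # no clipping
        assert np.array_equal(h1, h2)

    def test_out_of_bounds_patch_raises(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        with pytest.raises(ValueError, match="patch out of bounds"):
            pv.uniform_lbp_histogram(img, Keypoint(5, 5, 1, 0),
                                     LBPFilterConfig(patch_size=32))

    def test_matches_per_pixel_code_oracle(self, rng):
        img = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
        cfg = LBPFilterConfig(patch_size=10)
        kp = Keypoint(20, 20, 1, 0)
        h = pv.uniform_lbp_histogram(img, kp, cfg)
        window = img[15:25, 15:25]
        oracle = np.zeros(59)
        table = {c: (None if _transitions(c) > 2 else c) for c in range(256)}
        uniform_codes = sorted(c for c in range(256) if _transitions(c) <= 2)
        for r in range(1, 9):
            for c in range(1, 9):
                code = pv.lbp_code(window[r - 1:r + 2, c - 1:c + 2])
                idx = uniform_codes.index(code) if _transitions(code) <= 2 else 58
                oracle[idx] += 1
        assert np.array_equal(h, oracle)


class TestHistogramDistance:
    def test_identical_histograms_distance_zero(self, rng):
        h = rng.integers(0, 50, size=59).astype(float)
        for kind in HistogramDistance:
            assert pv.lbp_histogram_distance(h, h, kind) == 0.0

    def test_disjoint_one_hot_chi_square_closed_form(self):
        h1, h2 = np.zeros(59), np.zeros(59)
        h1[3] = 900
        h2[40] = 900
        assert pv.lbp_histogram_distance(h1, h2) == pytest.approx(2 * 900)

    def test_matches_brute_force_oracle(self, rng):
        h1 = rng.integers(0, 40, size=59).astype(float)
        h2 = rng.permutation(h1)  # equal total mass
        oracle = sum((a - b) ** 2 / (a + b) for a, b in zip(h1, h2) if a + b > 0)
        assert pv.lbp_histogram_distance(h1, h2) == pytest.approx(oracle)
        l1 = sum(abs(a - b) for a, b in zip(h1, h2))
        assert pv.lbp_histogram_distance(h1, h2, "l1") == pytest.approx(l1)
        inter = h1.sum() - sum(min(a, b) for a, b in zip(h1, h2))
        assert pv.lbp_histogram_distance(h1, h2, "intersection") == pytest.approx(inter)

    def test_mismatched_bin_counts_error(self):
        with pytest.raises(ValueError):
            pv.lbp_histogram_distance(np.zeros(59), np.zeros(10))


class TestNeighborFilter:
    def test_identical_geometry_all_kept(self):
        mask = square_mask((128, 128), 30, 30, 60)
        kps = [Keypoint(40, 40, 1, 0), Keypoint(70, 80, 1, 0)]
        out = pv.neighbor_filter(FilteredMatches.raw(pair_list(2)), kps, kps,
                                 mask, mask)
        assert out.labels == [MatchLabel.KEPT] * 2

    def test_pure_translation_all_kept(self):
        mask_a = square_mask((128, 128), 20, 20, 50)
        mask_b = square_mask((128, 128), 50, 60, 50)  # translated +30, +40
        kps_a = [Keypoint(30, 25, 1, 0), Keypoint(60, 65, 1, 0)]
        kps_b = [Keypoint(kp.x + 40, kp.y + 30, 1, 0) for kp in kps_a]
        out = pv.neighbor_filter(FilteredMatches.raw(pair_list(2)),
                                 kps_a, kps_b, mask_a, mask_b)
        assert out.labels == [MatchLabel.KEPT] * 2

    def test_displacement_beyond_pixel_threshold_removed(self):
        # centroids both (100, 100); kp_a (120, 100), kp_b (120, 130):
        # relative displacement 30 > threshold 15
        mask = square_mask((201, 201), 50, 50, 101)
        assert mask.centroid == (100.0, 100.0)
        cfg = NeighborFilterConfig(distance_threshold=15, scale_normalize=False)
        out = pv.neighbor_filter(
            FilteredMatches.raw([MatchPair(0, 0, 0.1, 0.5)]),
            [Keypoint(120, 100, 1, 0)], [Keypoint(120, 130, 1, 0)],
            mask, mask, cfg)
        assert out.labels == [MatchLabel.REMOVED_NEIGHBOR]

    def test_scale_normalized_invariance_under_rescaling(self):
        # mask B is mask A scaled 2x about the frame origin, keypoints too
        mask_a = square_mask((256, 256), 40, 40, 50)
        mask_b = square_mask((256, 256), 80, 80, 100)
        kps_a = [Keypoint(55.0, 50.0, 1, 0)]
        kps_b = [Keypoint(110.0, 100.0, 1, 0)]
        cfg = NeighborFilterConfig(distance_threshold=0.05, scale_normalize=True)
        out = pv.neighbor_filter(FilteredMatches.raw([MatchPair(0, 0, 0.1, 0.5)]),
                                 kps_a, kps_b, mask_a, mask_b, cfg)
        assert out.labels == [MatchLabel.KEPT]

    def test_empty_mask_errors(self):
        mask = square_mask((64, 64), 10, 10, 20)
        empty = square_mask((64, 64), 10, 10, 20)
        empty.area = 0
        with pytest.raises(ValueError):
            pv.neighbor_filter(FilteredMatches.raw([]), [], [], mask, empty)


def rendered_pair_with_features(seed=42):
    ident = pv.generate_identity(seed)
    img, _ = pv.render_sample(ident, pv.AcquisitionSpec(
        illumination_gradient=0.2, blur_sigma=1.0, noise_sigma=4.0, seed=3))
    feats = pv.extract_features(img)
    return feats


class TestLbpFilter:
    def test_self_pairs_all_kept_and_infinite_threshold_noop(self):
        f = rendered_pair_with_features()
        n = min(len(f.desc), 20)
        pairs = FilteredMatches.raw([MatchPair(i, i, 0.0, 0.0) for i in range(n)])
        out = pv.lbp_filter(pairs, f.enhanced, f.enhanced,
                            f.desc.keypoints, f.desc.keypoints)
        # identical patches -> distance 0 (pairs near the border are dropped)
        for label, reason in zip(out.labels, (out.reasons.get(i) for i in range(n))):
            assert label is MatchLabel.KEPT or reason == "patch out of bounds"
        loose = pv.lbp_filter(pairs, f.enhanced, f.enhanced,
                              f.desc.keypoints, f.desc.keypoints,
                              LBPFilterConfig(distance_threshold=1e18))
        for i, label in enumerate(loose.labels):
            assert label is MatchLabel.KEPT or loose.reasons[i] == "patch out of bounds"

    def test_only_kept_pairs_are_touched(self):
        f = rendered_pair_with_features()
        pairs = FilteredMatches(
            [MatchPair(0, 0, 0.0, 0.0), MatchPair(1, 1, 0.0, 0.0)],
            [MatchLabel.REMOVED_NEIGHBOR, MatchLabel.KEPT])
        out = pv.lbp_filter(pairs, f.enhanced, f.enhanced,
                            f.desc.keypoints, f.desc.keypoints)
        assert out.labels[0] is MatchLabel.REMOVED_NEIGHBOR


class TestHierarchicalFilter:
    def test_empty_input_empty_output(self):
        f = rendered_pair_with_features()
        out = pv.hierarchical_filter([], f.desc.keypoints, f.desc.keypoints,
                                     f.mask, f.mask, f.enhanced, f.enhanced)
        assert out.pairs == [] and out.labels == []

    def test_composition_equals_sequential_application(self):
        f = rendered_pair_with_features()
        rng = np.random.default_rng(0)
        n = len(f.desc)
        pairs = [MatchPair(int(i), int(rng.integers(0, n)), 0.5, 0.6)
                 for i in rng.integers(0, n, size=30)]
        combined = pv.hierarchical_filter(
            pairs, f.desc.keypoints, f.desc.keypoints, f.mask, f.mask,
            f.enhanced, f.enhanced)
        staged = pv.lbp_filter(
            pv.neighbor_filter(FilteredMatches.raw(pairs), f.desc.keypoints,
                               f.desc.keypoints, f.mask, f.mask),
            f.enhanced, f.enhanced, f.desc.keypoints, f.desc.keypoints)
        assert combined.labels == staged.labels

    def test_planted_outliers_removed(self):
        """Self-matched genuine pairs survive; >= 18 of 20 planted random
        cross-pairs (large displacement) are removed."""
        f = rendered_pair_with_features()
        xy = f.desc.xy
        n = len(f.desc)
        genuine = [MatchPair(i, i, 0.0, 0.0) for i in range(n)]
        rng = np.random.default_rng(99)
        planted = []
        while len(planted) < 20:
            i, j = rng.integers(0, n, size=2)
            if np.hypot(*(xy[i] - xy[j])) > 80:  # large displacement
                planted.append(MatchPair(int(i), int(j), 0.5, 0.6))
        out = pv.hierarchical_filter(genuine + planted,
                                     f.desc.keypoints, f.desc.keypoints,
                                     f.mask, f.mask, f.enhanced, f.enhanced)
        removed_planted = sum(1 for label in out.labels[n:]
                              if label is not MatchLabel.KEPT)
        assert removed_planted >= 18

    def test_filters_anti_extensive_and_idempotent(self):
        f = rendered_pair_with_features()
        rng = np.random.default_rng(1)
        n = len(f.desc)
        pairs = [MatchPair(int(i), int(rng.integers(0, n)), 0.5, 0.6)
                 for i in rng.integers(0, n, size=40)]
        once = pv.hierarchical_filter(pairs, f.desc.keypoints, f.desc.keypoints,
                                      f.mask, f.mask, f.enhanced, f.enhanced)
        assert once.kept_count <= len(pairs)
        again = pv.hierarchical_filter(once.kept, f.desc.keypoints,
                                       f.desc.keypoints, f.mask, f.mask,
                                       f.enhanced, f.enhanced)
        assert again.kept_count == once.kept_count
        assert all(l is MatchLabel.KEPT for l in again.labels)
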