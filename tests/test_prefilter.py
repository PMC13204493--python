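"""Stage-by-stage oracle tests and whole-chain detection properties."""

import numpy as np
import pytest

from carfind.imageio import Image
from carfind.prefilter import (
    PrefilterConfig,
    detect_candidates,
    disc_template,
    find_local_maxima,
    local_std_filter,
    match_filter,
    negative_threshold,
    radial_segment,
)
from conftest import blank_tile, cart_scene, match_candidates
from carfind.synth import render_tile


# ---------------------------------------------------------------- oracles


def std_filter_oracle(arr, window):
    """Per-pixel population SD over the reflect-padded window."""
    r = window // 2
    padded = np.pad(arr, r, mode="symmetric")  # edge-including reflection
    out = np.empty_like(arr, dtype=float)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            out[i, j] = padded[i : i + window, j : j + window].std()
    return out


def zncc_oracle(arr, template):
    """Sliding-window zero-mean normalized correlation, reflect-padded."""
    r = template.shape[0] // 2
    padded = np.pad(arr, r, mode="symmetric")
    t0 = template - template.mean()
    t_norm = np.sqrt((t0 * t0).sum())
    out = np.zeros(arr.shape, dtype=float)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            win = padded[i : i + template.shape[0], j : j + template.shape[1]]
            w0 = win - win.mean()
            den = np.sqrt((w0 * w0).sum()) * t_norm
            if den > 0:
                out[i, j] = (w0 * t0).sum() / den
    return out


def maxima_oracle(arr, min_distance):
    """Every strictly positive pixel maximal in its square neighborhood,
    greedily suppressed by descending score with (row, col) tie-break."""
    h, w = arr.shape
    d = min_distance
    qualifying = []
    for i in range(h):
        for j in range(w):
            v = arr[i, j]
            if v <= 0:
                continue
            neigh = arr[max(0, i - d) : i + d + 1, max(0, j - d) : j + d + 1]
            if v >= neigh.max():
                qualifying.append((i, j, v))
    qualifying.sort(key=lambda t: (-t[2], t[0], t[1]))
    accepted = []
    for i, j, v in qualifying:
        if all((i - ai) ** 2 + (j - aj) ** 2 >= d * d for ai, aj, _ in accepted):
            accepted.append((i, j, v))
    return accepted


# ---------------------------------------------------------- stage 1: SD


class TestLocalStdFilter:
    def test_constant_image_is_all_zero(self):
        out = local_std_filter(np.full((16, 16), 123.0), 5)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_single_hot_pixel_center_value(self):
        img = np.zeros((5, 5))
        img[2, 2] = 9.0
        out = local_std_filter(img, 3)
        # population SD of {9, 0 x 8}
        expected = np.std([9.0] + [0.0] * 8)
        assert out[2, 2] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(2.8284271, abs=1e-6)

    @pytest.mark.parametrize("window", [3, 5, 7])
    def test_matches_bruteforce_oracle(self, window, rng):
        for _ in range(5):
            img = rng.uniform(0, 1000, (16, 16))
            np.testing.assert_allclose(
                local_std_filter(img, window), std_filter_oracle(img, window), atol=1e-9
            )

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            local_std_filter(np.zeros((8, 8)), 4)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            local_std_filter(np.zeros((8, 8)), 9)


# -------------------------------------------------- stage 2: match filter


class TestMatchFilter:
    def small_config(self, radius=3, kind="disc"):
        return PrefilterConfig(
            template_radius_px=radius, template_kind=kind, min_peak_distance_px=3
        )

    def test_exact_template_copy_is_global_max(self):
        cfg = self.small_config()
        template = disc_template(3)
        arr = np.zeros((32, 32))
        arr[10:17, 20:27] = template
        corr = match_filter(arr, cfg)
        assert np.unravel_index(np.argmax(corr), corr.shape) == (13, 23)
        assert corr.max() == pytest.approx(1.0, abs=1e-9)

    def test_constant_input_scores_zero(self):
        corr = match_filter(np.full((32, 32), 500.0), self.small_config())
        np.testing.assert_allclose(corr, 0.0, atol=1e-9)

    @pytest.mark.parametrize("kind", ["disc", "annulus"])
    def test_matches_bruteforce_zncc_oracle(self, kind, rng):
        cfg = self.small_config(kind=kind)
        from carfind.prefilter import annulus_template

        template = disc_template(3) if kind == "disc" else annulus_template(3, 0.6)
        for _ in range(5):
            arr = rng.uniform(0, 100, (32, 32))
            np.testing.assert_allclose(
                match_filter(arr, cfg), zncc_oracle(arr, template), atol=1e-9
            )

    def test_output_bounded_by_unit_interval(self, rng):
        corr = match_filter(rng.uniform(0, 65535, (40, 40)), self.small_config())
        assert corr.min() >= -1.0 and corr.max() <= 1.0

    def test_template_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            match_filter(np.zeros((5, 5)), self.small_config(radius=10))


# ------------------------------------------------ stage 3: thresholding


class TestNegativeThreshold:
    def test_zeroes_negatives_keeps_rest(self):
        out = negative_threshold(np.array([-1.0, 0.0, 0.5]), 0.0)
        np.testing.assert_array_equal(out, [0.0, 0.0, 0.5])

    def test_all_negative_becomes_all_zero(self):
        out = negative_threshold(np.full((4, 4), -0.3), 0.0)
        assert np.all(out == 0.0)

    def test_positive_threshold_raises_the_cut(self):
        out = negative_threshold(np.array([0.1, 0.4]), 0.3)
        np.testing.assert_array_equal(out, [0.0, 0.4])

    def test_negative_threshold_clamps_to_zero(self):
        out = negative_threshold(np.array([-0.5, 0.2]), -2.0)
        np.testing.assert_array_equal(out, [0.0, 0.2])


# ------------------------------------------------- stage 4: local maxima


class TestFindLocalMaxima:
    def test_all_zero_grid_yields_nothing(self):
        assert find_local_maxima(np.zeros((10, 10)), 3) == []

    def test_single_positive_pixel_found(self):
        arr = np.zeros((10, 10))
        arr[4, 7] = 2.0
        assert find_local_maxima(arr, 3) == [(4, 7, 2.0)]

    def test_matches_greedy_suppression_oracle(self, rng):
        for _ in range(10):
            arr = np.round(rng.uniform(0, 10, (24, 24)), 1)
            arr[arr < 3] = 0.0  # plenty of zeros and ties
            assert find_local_maxima(arr, 3) == maxima_oracle(arr, 3)

    def test_sorted_by_descending_score(self, rng):
        arr = rng.uniform(0, 5, (30, 30))
        peaks = find_local_maxima(arr, 4)
        scores = [s for _, _, s in peaks]
        assert scores == sorted(scores, reverse=True)


# ---------------------------------------------- stage 5: radial segment


def _seg_config(**kw):
    defaults = dict(segment_radius_px=30, min_area_px=20, max_area_px=3000)
    defaults.update(kw)
    return PrefilterConfig(**defaults)


class TestRadialSegment:
    def test_disc_mask_area_close_to_analytic(self):
        arr = np.full((101, 101), 100.0)
        yy, xx = np.mgrid[0:101, 0:101]
        disc = np.hypot(yy - 50, xx - 50) <= 10
        arr[disc] += 50.0
        cands = radial_segment(arr, [(50, 50, 1.0)], _seg_config())
        assert len(cands) == 1
        assert cands[0].area_px == pytest.approx(np.pi * 100, rel=0.15)

    def test_flat_image_peak_discarded(self):
        arr = np.full((64, 64), 100.0)
        assert radial_segment(arr, [(32, 32, 1.0)], _seg_config()) == []

    def test_two_discs_give_disjoint_masks(self):
        arr = np.full((101, 151), 100.0)
        yy, xx = np.mgrid[0:101, 0:151]
        for cx in (50, 80):
            arr[np.hypot(yy - 50, xx - cx) <= 8] += 50.0
        cands = radial_segment(arr, [(50, 50, 1.0), (50, 80, 1.0)], _seg_config())
        assert len(cands) == 2
        footprints = []
        for cand in cands:
            full = np.zeros(arr.shape, dtype=bool)
            r0, c0 = cand.crop_origin
            full[r0 : r0 + cand.mask.shape[0], c0 : c0 + cand.mask.shape[1]] = cand.mask
            footprints.append(full)
        assert not np.any(footprints[0] & footprints[1])

    def test_peak_outside_image_rejected(self):
        with pytest.raises(ValueError):
            radial_segment(np.zeros((32, 32)), [(100, 5, 1.0)], _seg_config())

    def test_area_bounds_filter_candidates(self):
        arr = np.full((101, 101), 100.0)
        yy, xx = np.mgrid[0:101, 0:101]
        arr[np.hypot(yy - 50, xx - 50) <= 10] += 50.0
        tight = _seg_config(min_area_px=10, max_area_px=50)
        assert radial_segment(arr, [(50, 50, 1.0)], tight) == []


# --------------------------------------------------------- whole chain


class TestDetectCandidates:
    def test_blank_noise_tiles_yield_almost_no_candidates(self, rng):
        for _ in range(3):
            n = len(detect_candidates(Image(blank_tile(rng)), PrefilterConfig()))
            assert n <= 1

    def test_recall_on_sparse_cells_with_ground_truth(self):
        matched = total = 0
        for seed in range(3):
            img, truth = render_tile(cart_scene(20), seed=1500 + seed)
            cands = detect_candidates(img)
            matched += match_candidates(cands, truth.centers("CART"), radius_px=5.0)
            total += 20
        assert matched / total >= 0.9

    def test_contrast_inversion_preserves_detection(self):
        img, truth = render_tile(cart_scene(12), seed=321)
        inv, truth_inv = render_tile(
            cart_scene(12, invert_contrast=True), seed=321
        )
        n_normal = match_candidates(detect_candidates(img), truth.centers("CART"), 6)
        n_inv = match_candidates(detect_candidates(inv), truth_inv.centers("CART"), 6)
        assert abs(n_normal - n_inv) <= 2

    def test_translation_equivariance_on_crops(self):
        cfg = cart_scene(8, tile_px=(640, 640))
        img, truth = render_tile(cfg, seed=99)
        dr, dc = 7, 11
        view_a = Image(img.pixels[0:512, 0:512].copy())
        view_b = Image(img.pixels[dr : 512 + dr, dc : 512 + dc].copy())
        cands_a = detect_candidates(view_a)
        cands_b = detect_candidates(view_b)
        # objects well inside both crops must appear shifted by (dr, dc)
        inner = [
            c for c in cands_a
            if 100 < c.center[0] < 400 and 100 < c.center[1] < 400
        ]
        assert inner, "scene must contain interior detections"
        for cand in inner:
            shifted = (cand.center[0] - dr, cand.center[1] - dc)
            d = min(
                np.hypot(other.center[0] - shifted[0], other.center[1] - shifted[1])
                for other in cands_b
            )
            assert d <= 1.5

    def test_crowding_does_not_improve_recall(self):
        def mean_recall(n_cells, crowding, seeds):
            got = tot = 0
            for s in seeds:
                img, truth = render_tile(
                    cart_scene(n_cells, crowding=crowding), seed=7000 + s
                )
                got += match_candidates(
                    detect_candidates(img), truth.centers("CART"), 6
                )
                tot += n_cells
            return got / tot

        sparse = mean_recall(8, 110, range(3))
        crowded = mean_recall(24, 40, range(3))
        assert crowded <= sparse + 0.05
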