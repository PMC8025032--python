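"""Windowed entropy, rotational-SVD directionality, weighted entropy,
tumor segmentation, and angiogram modulation."""

import dataclasses
import math

import numpy as np
import pytest

import pactangio as pa
from pactangio import irregularity as irr


def _image(arr, h=0.1):
    return pa.MapImage(np.asarray(arr, float), h)


def oracle_rotate(window, theta_deg):
    """Independent per-pixel bilinear inverse-mapping rotation (pure loops)."""
    w = np.asarray(window, float)
    n = w.shape[0]
    c = (n - 1) / 2.0
    th = math.radians(theta_deg)
    out = np.zeros_like(w)
    for i in range(n):
        for j in range(n):
            dy, dx = i - c, j - c
            sy = c + math.cos(th) * dy + math.sin(th) * dx
            sx = c - math.sin(th) * dy + math.cos(th) * dx
            y0, x0 = math.floor(sy), math.floor(sx)
            fy, fx = sy - y0, sx - x0
            acc = 0.0
            for oy, ox, wt in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                               (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
                yy, xx = y0 + oy, x0 + ox
                if 0 <= yy < n and 0 <= xx < n:
                    acc += w[yy, xx] * wt
            out[i, j] = acc
    return out


def oracle_directionality(window, thetas):
    vals = []
    for th in thetas:
        s = np.linalg.svd(oracle_rotate(window, th), compute_uv=False)
        tot = s.sum()
        vals.append(1.0 if tot == 0 else s[0] / tot)
    return max(vals) - min(vals)


class TestEntropyMap:
    def test_constant_region_has_zero_entropy(self):
        px = np.zeros((50, 50))
        px[:25] = 0.8  # a single occupied bin per half, window well inside
        H = irr.entropy_map(_image(px), window_mm=1.0).entropy
        assert H[40, 25] == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_bins_give_one_bit(self):
        # vertical half-and-half window: P = (1/2, 1/2)
        px = np.zeros((40, 40))
        px[:, 20:] = 1.0
        H = irr.entropy_map(_image(px), window_mm=1.0, n_bins=32).entropy
        # center column sits between the halves; window is 10 px (even), so
        # the split is 50/50 at the column left of the boundary
        w = 10
        col = 20 + (w // 2 - 1) - w // 2 + 1  # even-window center convention
        candidates = H[20, 18:22]
        assert np.any(np.abs(candidates - 1.0) < 1e-9)

    def test_uniform_over_all_bins_reaches_log2_n(self):
        # 2x2 value tile: every 10x10 window holds exactly 25 px per bin
        n_bins = 4
        tile = np.array([[0.1, 0.35], [0.6, 0.85]])
        px = np.tile(tile, (20, 20))
        H = irr.entropy_map(_image(px), window_mm=1.0, n_bins=n_bins,
                            bin_max=1.0).entropy
        assert H[20, 20] == pytest.approx(math.log2(n_bins), abs=1e-9)

    def test_bounds_on_random_windows(self):
        """0 <= H <= log2(n_bins) over 1000 random windows."""
        rng = np.random.default_rng(0)
        for n_bins in (8, 32):
            for _ in range(5):
                px = rng.uniform(0, rng.uniform(0.5, 2.0), (100, 100))
                H = irr.entropy_map(_image(px), n_bins=n_bins).entropy  # 10^4 windows
                assert H.min() >= 0.0
                assert H.max() <= math.log2(n_bins) + 1e-12

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            irr.entropy_map(_image(np.ones((20, 20))), n_bins=1)


class TestNsvd:
    def test_rank_one_window_is_fully_dominant(self):
        w = np.outer(np.arange(1.0, 9.0), np.arange(2.0, 10.0))
        assert irr.nsvd(w, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_identity_window_equals_one_over_n(self):
        assert irr.nsvd(np.eye(7), 0.0) == pytest.approx(1.0 / 7.0, abs=1e-12)

    def test_diag_3_1_gives_three_quarters(self):
        assert irr.nsvd(np.diag([3.0, 1.0]), 0.0) == pytest.approx(0.75, abs=1e-12)

    def test_all_zero_window_convention(self):
        assert irr.nsvd(np.zeros((9, 9)), 30.0) == 1.0


class TestDirectionality:
    def test_radially_symmetric_window_has_near_zero_directionality(self):
        # A Gaussian blob is rotation invariant up to resampling smoothing;
        # bilinear interpolation is exact at 0/90 deg and smooths elsewhere,
        # leaving a small positive floor.
        n = 11
        yy, xx = np.meshgrid(np.arange(n) - 5, np.arange(n) - 5, indexing="ij")
        blob = np.exp(-(yy**2 + xx**2) / (2 * 1.5**2))
        d_blob = irr.directionality(blob)
        assert 0.0 <= d_blob < 0.12

    def test_line_window_far_exceeds_isotropic_window(self):
        n = 11
        line = np.zeros((n, n))
        line[5] = 1.0
        rng = np.random.default_rng(4)
        noise = rng.uniform(0, 1, (n, n))
        noise *= np.linalg.norm(line) / np.linalg.norm(noise)
        assert irr.directionality(line) > 2.0 * irr.directionality(noise)
        yy, xx = np.meshgrid(np.arange(n) - 5, np.arange(n) - 5, indexing="ij")
        blob = np.exp(-(yy**2 + xx**2) / (2 * 1.5**2))
        assert irr.directionality(line) > 3.0 * irr.directionality(blob)

    def test_matches_bruteforce_oracle_on_random_windows(self):
        """|D - D_bruteforce| < 1e-10 on 200 random 10x10 windows."""
        rng = np.random.default_rng(12)
        thetas = list(range(0, 180, 10))
        for _ in range(200):
            w = rng.uniform(0, 1, (10, 10))
            assert abs(irr.directionality(w, thetas)
                       - oracle_directionality(w, thetas)) < 1e-10

    def test_empty_theta_grid_rejected(self):
        with pytest.raises(ValueError):
            irr.directionality(np.ones((5, 5)), [])


class TestWeighting:
    def test_anisotropy_definition_and_monotonicity(self):
        assert irr.anisotropy(0.0) == pytest.approx(100.0)
        assert irr.anisotropy(0.99) == pytest.approx(1.0)
        d = np.linspace(0, 1, 50)
        assert np.all(np.diff(irr.anisotropy(d)) < 0)

    def test_zero_entropy_gives_zero_weighted_entropy(self):
        assert irr.weighted_entropy(0.0, 5.0) == 0.0

    def test_k_zero_disables_weighting(self):
        h = np.array([0.3, 1.7])
        assert np.allclose(irr.weighted_entropy(h, np.array([2.0, 50.0]), k=0.0), h)

    def test_high_directionality_window_suppressed_more(self):
        # healthy-like: D = 0.5 -> A ~ 1.96 ; tumor-like: D = 0.05 -> A ~ 16.7
        a_healthy = irr.anisotropy(0.5)
        a_tumor = irr.anisotropy(0.05)
        e_h = irr.weighted_entropy(1.0, a_healthy)
        e_t = irr.weighted_entropy(1.0, a_tumor)
        assert e_t > 100.0 * e_h

    def test_offset_reading_suppresses_the_opposite_windows(self):
        a_healthy = irr.anisotropy(0.5)
        a_tumor = irr.anisotropy(0.05)
        e_h = irr.weighted_entropy(1.0, a_healthy, reading="offset")
        e_t = irr.weighted_entropy(1.0, a_tumor, reading="offset")
        assert e_h > e_t  # the rejected reading favors healthy windows


class TestWeightedEntropyMap:
    def test_all_zero_map_gives_all_zero_E(self):
        mae = irr.weighted_entropy_map(_image(np.zeros((60, 60))), stride=2)
        assert np.all(mae.weighted_entropy == 0.0)

    def test_E_never_exceeds_H(self, t1_analysis):
        mae = t1_analysis["mae"]
        assert np.all(mae.weighted_entropy <= mae.entropy + 1e-12)
        assert np.all(mae.entropy <= math.log2(32) + 1e-12)

    def test_tumor_E_exceeds_healthy_E(self, t1_scene, t1_analysis):
        _, _, gt = t1_scene
        E = t1_analysis["mae"].weighted_entropy
        assert E[gt.tumor_mask].mean() > 3.0 * E[gt.healthy_mask].mean()

    def test_parallel_vessel_scene_is_suppressed(self):
        """A fully directional scene keeps at most 1% of its entropy."""
        px = np.zeros((200, 200))
        for x0 in range(20, 200, 20):
            px[:, x0 - 1:x0 + 2] = 1.0
        mae = irr.weighted_entropy_map(_image(px), stride=2)
        assert mae.weighted_entropy.max() <= 0.01 * mae.entropy.max()

    def test_map_centers_agree_with_scalar_operation(self, t1_analysis):
        """The vectorized map and the scalar windowed op share rotation and
        SVD conventions (margin-extracted patches, same theta grid)."""
        mpa = t1_analysis["mpa"]
        mae = t1_analysis["mae"]
        h = mpa.pixel_size_mm
        w = int(round(1.0 / h)) | 1
        p = int(math.ceil(w * math.sqrt(2)))
        if (p - w) % 2:
            p += 1
        pad = (p - 1) // 2
        padded = np.pad(mpa.pixels, pad)
        stride = 3  # pipeline default: D evaluated on strided centers
        for (i, j) in [(150, 150), (144, 132), (201, 198)]:
            patch = padded[i:i + p, j:j + p]
            d_scalar = max(
                irr.nsvd(irr.rotate_window(patch, th)[
                    (p - w) // 2:(p - w) // 2 + w, (p - w) // 2:(p - w) // 2 + w], 0.0)
                for th in range(0, 180, 10)) - min(
                irr.nsvd(irr.rotate_window(patch, th)[
                    (p - w) // 2:(p - w) // 2 + w, (p - w) // 2:(p - w) // 2 + w], 0.0)
                for th in range(0, 180, 10))
            assert mae.directionality[i, j] == pytest.approx(d_scalar, abs=5e-2)


class TestSegmentation:
    def _mae(self, E, h=0.1):
        return irr.WeightedEntropyMap(E, E, np.zeros_like(E), np.ones_like(E),
                                      30.0, 0.01, 1.0, h)

    def test_largest_component_selected(self):
        E = np.zeros((60, 60))
        E[5:17, 5:15] = 1.0   # 120 px
        E[40:49, 40:45] = 1.0  # 45 px
        mask = irr.segment_tumor(self._mae(E), sd_multiplier=1.4)
        assert mask.mask[10, 10]
        assert not mask.mask[44, 42]
        assert mask.mask.sum() == 120

    def test_empty_threshold_warns_and_returns_empty(self):
        E = np.ones((30, 30))  # zero SD, nothing strictly above mean
        with pytest.warns(UserWarning, match="empty"):
            mask = irr.segment_tumor(self._mae(E))
        assert not mask.mask.any()

    def test_scene_segmentation_centroid_near_tumor_center(self, t1_scene, t1_analysis):
        spec, _, gt = t1_scene
        tm = t1_analysis["tumor_mask"]
        assert tm.mask.any()
        ii, jj = np.nonzero(tm.mask)
        cy = (ii.mean() + 0.5) * 0.1
        cx = (jj.mean() + 0.5) * 0.1
        dist = math.hypot(cy - spec.tumor_center_mm[0], cx - spec.tumor_center_mm[1])
        assert dist < spec.tumor_radius_mm

    def test_complete_response_scene_has_no_residual_tumor_mask(self):
        spec = pa.VascularSceneSpec(seed=11, response_fraction=1.0)
        scene, gt = pa.make_vascular_scene(spec)
        res = pa.analyze_scene(scene, gt)
        tm = res["tumor_mask"].mask
        if tm.any():
            dice = 2 * (tm & gt.tumor_mask).sum() / (tm.sum() + gt.tumor_mask.sum())
            assert dice < 0.1

    def test_roi_E_nonincreasing_with_response(self):
        """Mean weighted entropy in the baseline ROI decreases as the tumor
        vasculature regresses (averaged over seeds)."""
        fractions = (0.0, 0.5, 1.0)
        means = np.zeros(len(fractions))
        for seed in (31, 32, 33):
            spec = pa.VascularSceneSpec(seed=seed)
            for k, f in enumerate(fractions):
                scene, gt = pa.make_vascular_scene(
                    dataclasses.replace(spec, response_fraction=f))
                res = pa.analyze_scene(scene, gt)
                means[k] += res["mae"].weighted_entropy[gt.tumor_mask].mean()
        assert means[0] > means[1] > means[2]


class TestDimensions:
    def _mask(self, m, h=0.1):
        return irr.TumorMask(np.asarray(m, bool), 0.0, h)

    def test_rectangle_reports_side_lengths(self):
        m = np.zeros((200, 200), bool)
        m[50:100, 30:130] = True  # 5 mm x 10 mm at 0.1 mm pixels
        dims = irr.tumor_dimensions(self._mask(m))
        assert dims.la_cm == pytest.approx(1.0, rel=0.02)
        assert dims.sa_cm == pytest.approx(0.5, rel=0.02)

    def test_single_pixel_mask(self):
        m = np.zeros((20, 20), bool)
        m[3, 4] = True
        dims = irr.tumor_dimensions(self._mask(m))
        assert dims.la_cm == pytest.approx(0.01)
        assert dims.sa_cm == pytest.approx(0.01)

    def test_circle_has_equal_axes(self):
        yy, xx = np.meshgrid(np.arange(200), np.arange(200), indexing="ij")
        m = (yy - 100) ** 2 + (xx - 100) ** 2 <= 60**2  # d = 12 mm
        dims = irr.tumor_dimensions(self._mask(m))
        assert dims.la_cm == pytest.approx(1.2, rel=0.03)
        assert dims.sa_cm == pytest.approx(1.2, rel=0.03)

    def test_slice_stack_volume(self):
        sl = np.zeros((50, 50), bool)
        sl[10:30, 10:30] = True  # 4 mm^2 at 0.1 mm pixels
        dims = irr.tumor_dimensions(self._mask(sl), per_slice_masks=[sl, sl, sl],
                                    slice_spacing_mm=1.0)
        assert dims.method == "slice_sum"
        assert dims.elevational_cm == pytest.approx(0.3)
        assert dims.volume_cm3 == pytest.approx(3 * 400 * 0.01 * 1.0 / 1000.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            irr.tumor_dimensions(self._mask(np.zeros((5, 5), bool)))


class TestModulation:
    def _mae_from(self, E, h=0.1):
        return irr.WeightedEntropyMap(E, E, np.zeros_like(E), np.ones_like(E),
                                      30.0, 0.01, 1.0, h)

    def test_zero_mae_retains_scaled_angiogram(self):
        rng = np.random.default_rng(5)
        mpa = rng.uniform(0.1, 1.0, (30, 30))
        out = irr.modulate(_image(mpa), self._mae_from(np.zeros((30, 30))))
        assert np.allclose(out.pixels, mpa / mpa.max())

    def test_tumor_to_background_weight_ratio(self):
        mpa = np.ones((40, 40))
        E = np.zeros((40, 40))
        E[10:20, 10:20] = 1.0
        out = irr.modulate(_image(mpa), self._mae_from(E), beta=0.07)
        ratio = out.pixels[15, 15] / out.pixels[0, 0]
        assert ratio == pytest.approx((1 + 0.07) / 0.07, rel=1e-9)

    def test_large_beta_recovers_angiogram(self):
        rng = np.random.default_rng(6)
        mpa = rng.uniform(0.1, 1.0, (20, 20))
        E = rng.uniform(0, 1, (20, 20))
        out = irr.modulate(_image(mpa), self._mae_from(E), beta=1e6)
        assert np.allclose(out.pixels, mpa / mpa.max(), rtol=1e-4)

    def test_additive_reading_available(self):
        mpa = np.ones((10, 10))
        E = np.zeros((10, 10))
        E[2, 2] = 1.0
        out = irr.modulate(_image(mpa), self._mae_from(E), beta=0.07,
                           reading="additive")
        assert out.pixels[2, 2] == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            irr.modulate(_image(np.ones((5, 5))), self._mae_from(np.zeros((6, 6))))
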