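"""Preprocessing: grayscale/Lab conversions, CLAHE and AHE oracles, pipeline."""

import numpy as np
import pytest

import foascope as f
from foascope import ClaheParams, EqualizationTemplate, ParameterError
from foascope.synthetic import render_fiber_lattice


# ---------------------------------------------------------------- oracles

def global_hist_eq(img, n_bins=256):
    """Plain global histogram equalization via explicit CDF (oracle)."""
    binned = np.minimum((img * n_bins).astype(int), n_bins - 1)
    hist = np.bincount(binned.ravel(), minlength=n_bins)
    cdf = np.cumsum(hist) / img.size
    return cdf[binned]


def clahe_oracle(img, num_tiles, clip_limit, n_bins=256):
    """Brute-force per-pixel tile-CDF + bilinear blend (independent oracle).

    Mirrors the documented contract: tiles are rounded-linspace
    partitions, each tile's histogram is clipped at clip_limit times the
    tile pixel count with one uniform redistribution pass, a pixel
    blends the two bracketing tile centers per axis and clamps at the
    borders.
    """
    rows, cols = img.shape
    tr, tc = num_tiles
    r_edges = np.round(np.linspace(0, rows, tr + 1)).astype(int)
    c_edges = np.round(np.linspace(0, cols, tc + 1)).astype(int)
    binned = np.minimum((img * n_bins).astype(int), n_bins - 1)

    cdfs = {}
    for i in range(tr):
        for j in range(tc):
            tile = binned[r_edges[i]: r_edges[i + 1], c_edges[j]: c_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=n_bins).astype(float)
            ceil = clip_limit * tile.size
            excess = np.clip(hist - ceil, 0, None).sum()
            hist = np.minimum(hist, ceil) + excess / n_bins
            cdfs[i, j] = np.cumsum(hist) / tile.size

    r_centers = [(r_edges[i] + r_edges[i + 1] - 1) / 2 for i in range(tr)]
    c_centers = [(c_edges[j] + c_edges[j + 1] - 1) / 2 for j in range(tc)]

    def bracket(pos, centers):
        if pos <= centers[0]:
            return 0, 0, 0.0
        if pos >= centers[-1]:
            return len(centers) - 1, len(centers) - 1, 0.0
        for k in range(len(centers) - 1):
            if centers[k] <= pos <= centers[k + 1]:
                w = (pos - centers[k]) / (centers[k + 1] - centers[k])
                return k, k + 1, w
        raise AssertionError

    out = np.empty_like(img, dtype=float)
    for y in range(rows):
        i0, i1, wy = bracket(y, r_centers)
        for x in range(cols):
            j0, j1, wx = bracket(x, c_centers)
            b = binned[y, x]
            out[y, x] = (
                (1 - wy) * (1 - wx) * cdfs[i0, j0][b]
                + (1 - wy) * wx * cdfs[i0, j1][b]
                + wy * (1 - wx) * cdfs[i1, j0][b]
                + wy * wx * cdfs[i1, j1][b]
            )
    return out


def ahe_oracle(img, h, w, n_bins=256):
    """Per-pixel window equalization by explicit enumeration (oracle)."""
    rows, cols = img.shape
    binned = np.minimum((img * n_bins).astype(int), n_bins - 1)
    out = np.empty_like(img, dtype=float)
    for y in range(rows):
        for x in range(cols):
            vals = []
            for dy in range(-(h // 2), h // 2 + 1):
                for dx in range(-(w // 2), w // 2 + 1):
                    yy = min(max(y + dy, 0), rows - 1)
                    xx = min(max(x + dx, 0), cols - 1)
                    vals.append(binned[yy, xx])
            out[y, x] = np.mean([v <= binned[y, x] for v in vals])
    return out


# ------------------------------------------------------------ conversions

class TestGrayscale:
    def test_gray_input_is_fixed_point(self):
        rgb = np.stack([np.full((4, 4), 113, np.uint8)] * 3, axis=-1)
        np.testing.assert_allclose(f.to_grayscale(rgb).pixels, 113 / 255)

    def test_black_and_white_endpoints(self):
        rgb = np.zeros((2, 2, 3), np.uint8)
        assert f.to_grayscale(rgb).pixels.max() == 0.0
        rgb[:] = 255
        assert f.to_grayscale(rgb).pixels.min() == 1.0

    def test_pure_red_bt601(self):
        rgb = np.zeros((1, 1, 3), np.uint8)
        rgb[..., 0] = 255
        # 0.299 * 255 = 76.245 rounds to 76 on the 8-bit scale
        assert f.to_grayscale(rgb).pixels[0, 0] == pytest.approx(76 / 255)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ParameterError):
            f.to_grayscale(np.zeros((4, 4, 4), np.uint8))


class TestLab:
    def test_round_trip_within_one_8bit_step(self, rng):
        rgb = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        L, a, b = f.rgb_to_lab(rgb)
        back = np.round(f.lab_to_rgb(L, a, b) * 255).astype(int)
        assert np.abs(back - rgb.astype(int)).max() <= 1

    def test_white_point(self):
        rgb = np.full((1, 1, 3), 255, np.uint8)
        L, a, b = f.rgb_to_lab(rgb)
        assert L[0, 0] == pytest.approx(100, abs=0.01)
        assert abs(a[0, 0]) < 0.01 and abs(b[0, 0]) < 0.01

    def test_neutral_ramp_has_no_chroma(self):
        ramp = np.stack([np.tile(np.arange(256, dtype=np.uint8), (2, 1))] * 3,
                        axis=-1)
        _, a, b = f.rgb_to_lab(ramp)
        assert np.abs(a).max() < 0.01 and np.abs(b).max() < 0.01


# ------------------------------------------------------------------ CLAHE

class TestClahe:
    def test_constant_image_stays_constant(self):
        out = f.clahe(np.full((30, 30), 0.4), ClaheParams(num_tiles=(3, 3)))
        assert np.ptp(out.pixels) < 1e-12

    def test_single_tile_unclipped_equals_global_equalization(self, rng):
        img = rng.random((32, 32))
        out = f.clahe(img, ClaheParams(num_tiles=(1, 1), clip_limit=1.0))
        np.testing.assert_allclose(out.pixels, global_hist_eq(img), atol=1e-12)

    def test_matches_brute_force_oracle_exactly(self, rng):
        # 8x8 two-valued image on a 2x2 tile grid, clipped.
        img = np.where(rng.random((8, 8)) < 0.4, 0.2, 0.7)
        params = ClaheParams(num_tiles=(2, 2), clip_limit=0.1)
        out = f.clahe(img, params)
        expected = clahe_oracle(img, (2, 2), 0.1)
        np.testing.assert_allclose(out.pixels, expected, atol=1e-12)

    def test_matches_oracle_on_random_image(self, rng):
        img = rng.random((12, 15))
        params = ClaheParams(num_tiles=(3, 2), clip_limit=0.2, n_bins=64)
        out = f.clahe(img, params)
        expected = clahe_oracle(img, (3, 2), 0.2, n_bins=64)
        np.testing.assert_allclose(out.pixels, expected, atol=1e-12)

    def test_rank_preserving_bin_shift_invariance(self, rng):
        # Shifting every pixel by a whole number of bins translates the
        # histograms without reordering them, so the output is unchanged.
        n_bins = 256
        img = rng.integers(0, 128, size=(20, 20)) / n_bins
        shifted = img + 64 / n_bins
        params = ClaheParams(num_tiles=(2, 2), clip_limit=0.3)
        np.testing.assert_allclose(
            f.clahe(img, params).pixels, f.clahe(shifted, params).pixels,
            atol=1e-12,
        )

    def test_single_tile_mapping_is_monotone(self, rng):
        img = rng.random((25, 25))
        out = f.clahe(img, ClaheParams(num_tiles=(1, 1), clip_limit=0.05)).pixels
        order = np.argsort(img.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= -1e-12)

    def test_image_smaller_than_tile_grid_rejected(self):
        with pytest.raises(ParameterError):
            f.clahe(np.zeros((10, 10)), ClaheParams(num_tiles=(25, 25)))

    def test_clip_limit_range_enforced(self):
        with pytest.raises(ParameterError):
            ClaheParams(clip_limit=0.001)


class TestMovingWindowEqualize:
    def test_constant_image_stays_constant(self):
        out = f.moving_window_equalize(
            np.full((9, 9), 0.6), EqualizationTemplate(3, 3)
        )
        assert np.ptp(out.pixels) < 1e-12

    def test_matches_enumeration_oracle(self, rng):
        img = rng.integers(0, 8, size=(5, 5)) / 8.0
        out = f.moving_window_equalize(img, EqualizationTemplate(3, 3, n_bins=8))
        np.testing.assert_allclose(out.pixels, ahe_oracle(img, 3, 3, n_bins=8),
                                   atol=1e-12)

    def test_full_window_collapses_to_global_equalization_at_center(self, rng):
        img = rng.random((9, 9))
        out = f.moving_window_equalize(img, EqualizationTemplate(9, 9))
        assert out.pixels[4, 4] == pytest.approx(global_hist_eq(img)[4, 4],
                                                 abs=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ParameterError):
            EqualizationTemplate(4, 3)

    def test_agrees_with_clahe_on_slow_ramp(self):
        # Window roughly matching the tile pitch: the two local
        # equalizers agree away from the borders (documented tolerance,
        # not exact — border conventions differ).
        yy, xx = np.mgrid[0:64, 0:64] / 63.0
        img = 0.3 + 0.4 * (0.5 * yy + 0.5 * xx)
        c = f.clahe(img, ClaheParams(num_tiles=(4, 4), clip_limit=1.0)).pixels
        a = f.moving_window_equalize(img, EqualizationTemplate(17, 17)).pixels
        inner = np.s_[8:-8, 8:-8]
        assert np.abs(c[inner] - a[inner]).max() < 0.15
        assert np.abs(c[inner] - a[inner]).mean() < 0.05


# --------------------------------------------------------------- pipeline

class TestPipeline:
    def test_constant_rgb_gives_constant_output(self):
        rgb = np.full((30, 30, 3), 120, np.uint8)
        out = f.preprocess_pipeline(rgb, ClaheParams(num_tiles=(3, 3)))
        assert np.ptp(out.pixels) < 1e-9

    def test_neutral_axis_collapse_to_gray_clahe(self, small_scene):
        # Replicated-gray input: the Lab route equals CLAHE on the gray
        # channel up to binning differences between the L* and gray axes.
        rgb = np.stack([small_scene.image] * 3, axis=-1)
        via_lab = f.preprocess_pipeline(rgb).pixels
        direct = f.clahe(f.to_grayscale(rgb)).pixels
        assert np.abs(via_lab - direct).max() < 0.06
        assert np.abs(via_lab - direct).mean() < 0.02

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_illumination_flatness_improves(self, seed):
        scene = f.default_scene(seed=seed, shape=(256, 256), n_live=4, n_dead=4)
        img = scene.image_float
        pre = f.preprocess_pipeline(np.stack([scene.image] * 3, axis=-1)).pixels

        def flatness(a):
            q = a.shape[0] // 4
            center = a[q:-q, q:-q].mean()
            border = (a.sum() - a[q:-q, q:-q].sum()) / (a.size - a[q:-q, q:-q].size)
            return center / border

        assert abs(flatness(pre) - 1) < abs(flatness(img) - 1)

    def test_cell_contrast_enhanced_and_beats_gap_artifact(self, small_scene):
        # The live-cell interior-vs-rim contrast must not decrease, and
        # its margin over the core/gap lattice contrast must widen:
        # after preprocessing the cells stand out more than the strongest
        # artifact, even though equalization also stretches the lattice.
        img = small_scene.image_float
        pre = f.preprocess_pipeline(np.stack([small_scene.image] * 3, axis=-1)).pixels
        gain = render_fiber_lattice(small_scene.lattice, img.shape)
        yy, xx = np.mgrid[0: img.shape[0], 0: img.shape[1]]
        cellfree = np.ones(img.shape, bool)
        contrasts = {"before": [], "after": []}
        for c in small_scene.gt:
            d = np.hypot(yy - c.y, xx - c.x)
            cellfree &= d > c.radius_px + 2
            if c.label != "live":
                continue
            interior = d <= c.radius_px - small_scene.population.rim_thickness_px
            rim = (d <= c.radius_px) & ~interior
            contrasts["before"].append(img[interior].mean() - img[rim].mean())
            contrasts["after"].append(pre[interior].mean() - pre[rim].mean())
        core = (gain == small_scene.lattice.core_gain) & cellfree
        gap = (gain != small_scene.lattice.core_gain) & cellfree
        gap_before = abs(img[core].mean() - img[gap].mean())
        gap_after = abs(pre[core].mean() - pre[gap].mean())
        cell_before = np.mean(contrasts["before"])
        cell_after = np.mean(contrasts["after"])
        assert cell_after >= cell_before
        assert cell_after - gap_after > cell_before - gap_before
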