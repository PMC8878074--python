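"""Normalization, wavelet denoising, tiling and augmentation."""

import numpy as np
import pytest
import pywt
from scipy.signal import convolve2d

from cbaseg.preprocess import (
    assemble_tiles,
    augment_stream,
    make_epoch,
    normalize_image,
    read_dsb_masks,
    relabel_sequential,
    tile_image,
    wavelet_lowpass,
)


class TestNormalizeImage:
    def test_rgb_slide_to_gray_192(self):
        rng = np.random.default_rng(0)
        img = (rng.random((1000, 1000, 3)) * 255).astype(np.uint8)
        out = normalize_image(img)
        assert out.shape == (192, 192)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_already_normalized_input_unchanged(self):
        rng = np.random.default_rng(1)
        img = rng.random((192, 192))
        np.testing.assert_allclose(normalize_image(img), img, atol=1e-12)

    def test_constant_rgb_maps_to_same_gray(self):
        img = np.full((64, 64, 3), 0.4)
        out = normalize_image(img)
        np.testing.assert_allclose(out, 0.4, atol=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        img = (rng.random((300, 400, 3)) * 255).astype(np.uint8)
        once = normalize_image(img)
        np.testing.assert_allclose(normalize_image(once), once, atol=1e-12)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            normalize_image(np.zeros((0, 10)))

    def test_alpha_channel_dropped(self):
        img = np.dstack([np.full((64, 64, 3), 0.25), np.ones((64, 64))])
        np.testing.assert_allclose(normalize_image(img), 0.25, atol=1e-6)


class TestWaveletLowpass:
    def test_reduces_white_noise_variance(self):
        rng = np.random.default_rng(0)
        img = np.clip(0.5 + rng.normal(0, 0.1, (128, 128)), 0, 1)
        out = wavelet_lowpass(img)
        assert out.var() < img.var()

    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 0.3)
        np.testing.assert_allclose(wavelet_lowpass(img), 0.3, atol=1e-10)

    def test_tiny_image_returned_unchanged_with_warning(self):
        img = np.random.default_rng(0).random((4, 4))
        with pytest.warns(UserWarning):
            out = wavelet_lowpass(img)
        np.testing.assert_array_equal(out, img)

    def test_variance_reduction_matches_independent_filter_bank(self):
        """Noisy disk image: compare against a from-scratch separable DWT
        (periodized filter bank) applying the same universal soft threshold."""
        rng = np.random.default_rng(5)
        yy, xx = np.mgrid[0:64, 0:64]
        clean = 0.15 + 0.7 * (((yy - 32) ** 2 + (xx - 32) ** 2) < 18 ** 2)
        img = np.clip(clean + rng.normal(0, 0.08, clean.shape), 0, 1)

        out_pkg = wavelet_lowpass(img, "bior1.3")

        wav = pywt.Wavelet("bior1.3")
        out_ind = _dwt_denoise_periodized(img, wav)
        ratio_pkg = out_pkg.var() / img.var()
        ratio_ind = out_ind.var() / img.var()
        assert ratio_pkg < 1.0
        # boundary handling differs (symmetric vs periodic), everything else
        # is identical, so the global variance-reduction ratios agree closely
        assert abs(ratio_pkg - ratio_ind) < 0.05


def _dwt_denoise_periodized(img, wav):
    """One-level 2-D DWT + universal soft threshold, by explicit separable
    circular convolution with the wavelet's filter banks."""

    def conv_down(x, f, axis):
        f = np.asarray(f)[::-1]
        k = np.zeros((1, 1))
        if axis == 0:
            out = np.zeros_like(x)
            for i, c in enumerate(f):
                out += c * np.roll(x, -(i - len(f) + 1), axis=0)
            return out[::2]
        out = np.zeros_like(x)
        for i, c in enumerate(f):
            out += c * np.roll(x, -(i - len(f) + 1), axis=1)
        return out[:, ::2]

    def up_conv(x, f, axis, n):
        f = np.asarray(f)
        if axis == 0:
            ups = np.zeros((n, x.shape[1]))
            ups[::2] = x
        else:
            ups = np.zeros((x.shape[0], n))
            ups[:, ::2] = x
        out = np.zeros_like(ups)
        for i, c in enumerate(f):
            out += c * np.roll(ups, i - len(f) + 1, axis=axis)
        return out

    lo, hi = wav.dec_lo, wav.dec_hi
    rlo, rhi = wav.rec_lo, wav.rec_hi
    a = conv_down(conv_down(img, lo, 0), lo, 1)
    h = conv_down(conv_down(img, lo, 0), hi, 1)
    v = conv_down(conv_down(img, hi, 0), lo, 1)
    d = conv_down(conv_down(img, hi, 0), hi, 1)
    sigma = np.median(np.abs(d)) / 0.6745
    thr = sigma * np.sqrt(2 * np.log(img.size))
    soft = lambda c: np.sign(c) * np.maximum(np.abs(c) - thr, 0)
    h, v, d = soft(h), soft(v), soft(d)
    n0, n1 = img.shape
    rec = (up_conv(up_conv(a, rlo, 1, n1), rlo, 0, n0)
           + up_conv(up_conv(h, rhi, 1, n1), rlo, 0, n0)
           + up_conv(up_conv(v, rlo, 1, n1), rhi, 0, n0)
           + up_conv(up_conv(d, rhi, 1, n1), rhi, 0, n0))
    return np.clip(rec, 0, 1)


class TestTileImage:
    def test_1000px_slide_gives_16_patches(self):
        img = np.random.default_rng(0).random((1000, 1000))
        tiles, grid = tile_image(img, patch=250)
        assert len(tiles) == 16 and grid.n_patches == 16
        assert all(t.shape == (250, 250) for t in tiles)

    def test_single_patch_identity(self):
        img = np.random.default_rng(1).random((250, 250))
        tiles, grid = tile_image(img, patch=250)
        assert len(tiles) == 1
        np.testing.assert_array_equal(tiles[0], img)

    def test_rectangular_slide_reassembles_exactly(self):
        img = np.random.default_rng(2).random((500, 750))
        tiles, grid = tile_image(img, patch=250)
        assert len(tiles) == 6 and (grid.rows, grid.cols) == (2, 3)
        np.testing.assert_array_equal(assemble_tiles(tiles, grid), img)

    def test_non_divisible_side_padded_and_recorded(self):
        img = np.random.default_rng(3).random((300, 260))
        tiles, grid = tile_image(img, patch=250)
        assert (grid.rows, grid.cols) == (2, 2)
        assert (grid.pad_bottom, grid.pad_right) == (200, 240)
        np.testing.assert_array_equal(assemble_tiles(tiles, grid), img)

    def test_mask_patches_relabeled_contiguously(self):
        img = np.zeros((500, 500))
        mask = np.zeros((500, 500), int)
        mask[10:40, 10:40] = 7          # only label in its tile -> becomes 1
        mask[300:340, 300:340] = 3
        tiles, grid = tile_image(img, mask, patch=250)
        mask_patches = [m for _, m in tiles]
        assert set(np.unique(mask_patches[0])) == {0, 1}
        assert set(np.unique(mask_patches[3])) == {0, 1}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tile_image(np.zeros((100, 100)), np.zeros((50, 50), int))


class TestAugmentStream:
    @staticmethod
    def tiny_dataset(n=3, size=32, seed=0):
        rng = np.random.default_rng(seed)
        data = []
        for _ in range(n):
            img = rng.random((size, size))
            mask = np.zeros((size, size), int)
            mask[4:10, 4:10] = 1
            mask[20:26, 12:18] = 2
            data.append((img, mask))
        return data

    def test_identical_seeds_reproduce_identical_streams(self):
        data = self.tiny_dataset()
        s1 = augment_stream(data, seed=11, out_size=16)
        s2 = augment_stream(data, seed=11, out_size=16)
        for _ in range(5):
            i1, m1 = next(s1)
            i2, m2 = next(s2)
            np.testing.assert_array_equal(i1, i2)
            np.testing.assert_array_equal(m1, m2)

    def test_axis_aligned_draws_preserve_instance_pixel_counts(self):
        # free-angle off and crop size equal to the image: every transform
        # is a permutation of pixels, so per-instance areas are invariant
        data = self.tiny_dataset(size=32)
        stream = augment_stream(data, seed=3, out_size=32, free_angle_prob=0.0)
        base_counts = {tuple(sorted(np.bincount(m.ravel())[1:])) for _, m in data}
        for _ in range(10):
            _, m = next(stream)
            counts = tuple(sorted(np.bincount(m.ravel())[1:]))
            assert counts in base_counts

    def test_epoch_preset_reaches_the_configured_size(self):
        # 536 sources expanded to a fixed 2372-crop epoch
        data = self.tiny_dataset(n=536, size=16)
        epoch = make_epoch(data, 2372, seed=0, out_size=16, free_angle_prob=0.0)
        assert len(epoch) == 2372

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            next(augment_stream([], seed=0))


class TestReaders:
    def test_dsb_mask_directory_union(self, tmp_path):
        import imageio.v3 as iio

        d = tmp_path / "masks"
        d.mkdir()
        m1 = np.zeros((20, 20), np.uint8)
        m1[2:6, 2:6] = 255
        m2 = np.zeros((20, 20), np.uint8)
        m2[10:15, 10:15] = 255
        iio.imwrite(d / "a.png", m1)
        iio.imwrite(d / "b.png", m2)
        labels = read_dsb_masks(d)
        assert set(np.unique(labels)) == {0, 1, 2}
        assert (labels[2:6, 2:6] == 1).all() and (labels[10:15, 10:15] == 2).all()

    def test_overlapping_instances_rejected(self, tmp_path):
        import imageio.v3 as iio

        d = tmp_path / "masks"
        d.mkdir()
        m = np.zeros((10, 10), np.uint8)
        m[2:6, 2:6] = 255
        iio.imwrite(d / "a.png", m)
        iio.imwrite(d / "b.png", m)
        with pytest.raises(ValueError):
            read_dsb_masks(d)


def test_relabel_sequential_closes_gaps():
    m = np.array([[0, 5], [9, 5]])
    out = relabel_sequential(m)
    assert set(np.unique(out)) == {0, 1, 2}
    assert out[0, 1] == out[1, 1] == 1 and out[1, 0] == 2
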