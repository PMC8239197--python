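"""Codec correctness (against an independent PNG implementation) and the
PNG-Rate / rotate-and-recompress estimators."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from PIL import Image

from entropix.shannon_direct import TrialMatrix
from entropix.png_codec import (
    GrayImage,
    PngFormatError,
    decode_png,
    encode_png,
    matrix_to_image,
    mi_png_rate,
    normalize_to_8bit,
    png_overhead,
    png_rate,
    rotate90,
)


class TestNormalize:
    def test_midpoint_rounds_half_up(self):
        assert normalize_to_8bit([-70, -20, 30]).tolist() == [0, 128, 255]

    def test_constant_maps_to_zero(self):
        assert normalize_to_8bit([5, 5, 5]).tolist() == [0, 0, 0]

    def test_full_range_fixed_points(self):
        assert normalize_to_8bit([0, 255]).tolist() == [0, 255]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_8bit([1.0, np.inf])


class TestEncodeDecode:
    def test_all_zero_100x100_is_90_bytes(self):
        assert png_overhead(100, 100, 8) == 90

    def test_one_pixel_layout(self):
        data = encode_png(GrayImage(np.zeros((1, 1), dtype=np.uint8)))
        # 57 bytes of fixed layout plus the DEFLATE payload
        assert len(data) == 57 + len(data) - 57
        assert data[:8] == b"\x89PNG\r\n\x1a\n"
        img = decode_png(data)
        assert img.pixels.shape == (1, 1)

    @pytest.mark.parametrize("depth,shape", [
        (8, (31, 17)), (8, (1, 300)), (1, (13, 21)), (1, (5, 9)),
    ])
    def test_roundtrip_identity(self, depth, shape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        px = rng.integers(0, 2**depth, shape).astype(np.uint8)
        img = GrayImage(px, depth)
        out = decode_png(encode_png(img))
        assert out.bit_depth == depth
        assert np.array_equal(out.pixels, px)

    def test_pillow_decodes_our_files(self):
        rng = np.random.default_rng(2)
        px = rng.integers(0, 256, (40, 23)).astype(np.uint8)
        data = encode_png(GrayImage(px, 8))
        assert np.array_equal(np.array(Image.open(io.BytesIO(data))), px)

    def test_pillow_decodes_our_1bit_files(self):
        rng = np.random.default_rng(3)
        px = rng.integers(0, 2, (11, 19)).astype(np.uint8)
        data = encode_png(GrayImage(px, 1))
        ref = np.array(Image.open(io.BytesIO(data)).convert("L")) // 255
        assert np.array_equal(ref, px)

    def test_we_decode_pillow_files(self):
        rng = np.random.default_rng(4)
        px = rng.integers(0, 256, (27, 31)).astype(np.uint8)
        buf = io.BytesIO()
        Image.fromarray(px, "L").save(buf, "PNG")
        assert np.array_equal(decode_png(buf.getvalue()).pixels, px)

    def test_corrupted_crc_rejected(self):
        data = bytearray(encode_png(GrayImage(np.zeros((4, 4), dtype=np.uint8))))
        data[40] ^= 0xFF  # inside the IDAT chunk
        with pytest.raises(PngFormatError):
            decode_png(bytes(data))

    def test_truncated_stream_rejected(self):
        data = encode_png(GrayImage(np.zeros((4, 4), dtype=np.uint8)))
        with pytest.raises(PngFormatError):
            decode_png(data[:-6])

    def test_rgb_input_rejected(self):
        buf = io.BytesIO()
        Image.new("RGB", (5, 5)).save(buf, "PNG")
        with pytest.raises(PngFormatError):
            decode_png(buf.getvalue())

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(1, 40), st.integers(1, 40), st.integers(0, 2**31 - 1),
           st.sampled_from([1, 8]))
    def test_roundtrip_property(self, w, h, seed, depth):
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 2**depth, (h, w)).astype(np.uint8)
        out = decode_png(encode_png(GrayImage(px, depth)))
        assert np.array_equal(out.pixels, px)


class TestOverhead:
    def test_constant_images_sit_near_the_floor(self):
        # non-zero constants cost a few extra DEFLATE bytes (the literal is
        # no longer the all-zero run) but stay within tens of bytes of the
        # all-zero floor and far below any structured content
        for value in (0, 7, 255):
            img = GrayImage(np.full((100, 100), value, dtype=np.uint8))
            assert 90 <= len(encode_png(img)) <= 130

    def test_overhead_grows_sublinearly(self):
        assert png_overhead(200, 200) < 4 * png_overhead(100, 100)

    def test_blank_rate_is_overhead_over_pixels(self):
        img = GrayImage(np.zeros((50, 50), dtype=np.uint8))
        res = png_rate(img)
        assert res.rate_bytes_per_pixel == res.file_bytes / 2500
        assert res.file_bytes == png_overhead(50, 50)


class TestRotate:
    def test_matches_index_permutation_oracle(self):
        img = GrayImage(np.arange(6, dtype=np.uint8).reshape(2, 3))
        rot = rotate90(img)
        assert rot.pixels.shape == (3, 2)
        for r in range(2):
            for c in range(3):
                # clockwise: (r, c) -> (c, height-1-r)
                assert rot.pixels[c, 2 - 1 - r] == img.pixels[r, c]

    def test_four_rotations_are_identity(self):
        rng = np.random.default_rng(5)
        img = GrayImage(rng.integers(0, 256, (7, 11)).astype(np.uint8))
        out = img
        for _ in range(4):
            out = rotate90(out)
        assert np.array_equal(out.pixels, img.pixels)

    def test_square_constant_unchanged(self):
        img = GrayImage(np.full((6, 6), 9, dtype=np.uint8))
        assert np.array_equal(rotate90(img).pixels, img.pixels)


class TestPngRate:
    def test_binary_noise_rate_near_017(self):
        rates = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            px = (rng.integers(0, 2, (100, 100)) * 255).astype(np.uint8)
            rates.append(png_rate(GrayImage(px)).rate_bytes_per_pixel)
        assert np.mean(rates) == pytest.approx(0.17, abs=0.02)

    def test_sampling_rate_scaling(self):
        img = GrayImage(np.zeros((10, 10), dtype=np.uint8))
        res = png_rate(img, sampling_rate=1000.0)
        assert res.rate_bytes_per_s == pytest.approx(res.rate_bytes_per_pixel * 1000)

    def test_rate_monotone_in_alphabet_size(self):
        rng = np.random.default_rng(0)
        rates = []
        for v in (2, 4, 8, 16, 32, 64, 128, 256):
            vals = np.round(np.arange(v) * 255.0 / (v - 1)).astype(np.uint8)
            px = vals[rng.integers(0, v, (100, 100))]
            rates.append(png_rate(GrayImage(px)).rate_bytes_per_pixel)
        assert all(a < b for a, b in zip(rates, rates[1:]))


class TestMiPngRate:
    def test_identical_long_rows_noise_near_floor(self):
        # rows longer than the 32-KiB DEFLATE window: the signal image pays
        # the content once per trial, the rotated image only once, so
        # perfectly reproducible trials push the difference toward the
        # signal rate
        rng = np.random.default_rng(6)
        row = rng.integers(0, 256, 40_000).astype(float)
        tm = TrialMatrix(np.tile(row, (8, 1)), sampling_rate=1.0)
        res = mi_png_rate(tm, bit_depth=8)
        assert res.difference == pytest.approx(res.signal_rate - res.noise_rate)
        assert res.noise_rate < 0.3 * res.signal_rate
        assert res.difference > 0.5 * res.signal_rate

    @pytest.mark.parametrize("seed", range(3))
    def test_iid_binary_matrix_difference_small(self, seed):
        rng = np.random.default_rng(seed)
        tm = TrialMatrix(rng.integers(0, 2, (100, 100)).astype(float))
        res = mi_png_rate(tm, bit_depth=1)
        assert abs(res.difference) <= 0.02 * res.signal_rate

    def test_difference_grows_with_trial_reliability(self):
        """Frozen pattern with increasing flip noise: MI proxy decreases."""
        rng = np.random.default_rng(7)
        base = rng.integers(0, 2, (1, 2000)).astype(float)
        diffs = []
        for p_flip in (0.0, 0.2, 0.5):
            rows = np.tile(base, (20, 1))
            flips = rng.random(rows.shape) < p_flip
            rows[flips] = 1 - rows[flips]
            diffs.append(mi_png_rate(TrialMatrix(rows), 1).difference)
        assert diffs[0] > diffs[1] > diffs[2]

    def test_rotation_convention_does_not_change_difference(self):
        from entropix.png_codec import GrayImage, png_rate

        rng = np.random.default_rng(8)
        tm = TrialMatrix(rng.integers(0, 2, (50, 80)).astype(float))
        res = mi_png_rate(tm, bit_depth=1)
        img = matrix_to_image(tm, 1)
        ccw = GrayImage(np.rot90(img.pixels, k=1), 1)
        diff_ccw = (png_rate(img, sampling_rate=1.0).rate_bytes_per_s
                    - png_rate(ccw, sampling_rate=1.0).rate_bytes_per_s)
        assert abs(res.difference - diff_ccw) <= 0.005 * max(res.signal_rate, 1)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            mi_png_rate(TrialMatrix(np.zeros((1, 10))), 8)

    def test_nonbinary_matrix_rejected_at_depth_1(self):
        tm = TrialMatrix(np.arange(20, dtype=float).reshape(2, 10))
        with pytest.raises(ValueError):
            matrix_to_image(tm, 1)


class TestGrayImageValidation:
    def test_pixel_range_enforced(self):
        with pytest.raises(ValueError):
            GrayImage(np.array([[0, 2]]), bit_depth=1)

    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            GrayImage(np.zeros((2, 2), dtype=np.uint8), bit_depth=4)
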