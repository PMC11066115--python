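import json

import numpy as np
import pytest
import tifffile
from hypothesis import given
from hypothesis import strategies as st

from camangio import (
    CineLoop,
    CineIOError,
    PointAnnotation,
    RoiMask,
    ValidationError,
    read_annotations,
    read_cine,
    read_image,
    write_annotations,
    write_cine,
    write_image,
)
from camangio.cine_io import mask_to_rle, rle_to_mask


class TestReadCine:
    def test_dtype_maximum_normalization(self, tmp_path):
        """8-bit saturated frames normalize to exactly 1.0, never per-file min/max."""
        path = tmp_path / "sat.tif"
        tifffile.imwrite(path, np.full((3, 8, 8), 255, dtype=np.uint8), photometric="minisblack")
        loop = read_cine(path, normalize=True)
        assert loop.n_frames == 3
        assert np.all(loop.frames == 1.0)

    def test_16bit_normalization(self, tmp_path):
        path = tmp_path / "u16.tif"
        tifffile.imwrite(path, np.full((2, 4, 4), 65535, dtype=np.uint16))
        assert np.all(read_cine(path).frames == 1.0)

    def test_tiff_roundtrip_bit_exact(self, tmp_path, rng):
        values = rng.integers(0, 256, size=(6, 20, 30))
        loop = CineLoop(frames=values / 255.0)
        path = tmp_path / "loop.tif"
        write_cine(loop, path, bit_depth=8)
        assert np.array_equal(read_cine(path).frames, loop.frames)

    def test_avi_roundtrip_bit_exact(self, tmp_path, rng):
        values = rng.integers(0, 256, size=(6, 21, 33))  # odd width exercises row padding
        loop = CineLoop(frames=values / 255.0, frame_rate_hz=25.0)
        path = tmp_path / "loop.avi"
        write_cine(loop, path, bit_depth=8)
        back = read_cine(path)
        assert np.array_equal(back.frames, loop.frames)
        assert back.frame_rate_hz == 25.0

    def test_rgb_equals_channel_average_oracle(self, tmp_path, rng):
        gray = rng.integers(0, 256, size=(4, 10, 12), dtype=np.uint8)
        rgb = np.stack([gray] * 3, axis=-1)
        p_gray, p_rgb = tmp_path / "g.tif", tmp_path / "c.tif"
        tifffile.imwrite(p_gray, gray, photometric="minisblack")
        tifffile.imwrite(p_rgb, rgb)
        np.testing.assert_array_equal(
            read_cine(p_rgb).frames, read_cine(p_gray).frames
        )
        # non-equal channels follow the explicit channel-mean oracle
        rgb2 = rng.integers(0, 256, size=(3, 6, 6, 3), dtype=np.uint8)
        p2 = tmp_path / "c2.tif"
        tifffile.imwrite(p2, rgb2)
        oracle = rgb2.astype(float).mean(axis=-1) / 255.0
        np.testing.assert_allclose(read_cine(p2).frames, oracle, atol=1e-12)

    def test_missing_file_is_io_error(self, tmp_path):
        with pytest.raises(CineIOError, match="nope.tif"):
            read_cine(tmp_path / "nope.tif")

    def test_single_frame_is_validation_error(self, tmp_path):
        path = tmp_path / "one.tif"
        tifffile.imwrite(path, np.zeros((8, 8), dtype=np.uint8))
        with pytest.raises(ValidationError, match="T >= 2"):
            read_cine(path)

    def test_normalization_idempotent_on_float_files(self, tmp_path, rng):
        frames = rng.random((3, 8, 8))
        path = tmp_path / "float.tif"
        tifffile.imwrite(path, frames.astype(np.float64), photometric="minisblack")
        np.testing.assert_array_equal(read_cine(path, normalize=True).frames, frames)


class TestCineLoopValidation:
    def test_too_few_frames(self):
        with pytest.raises(ValidationError):
            CineLoop(frames=np.zeros((1, 4, 4)))

    def test_negative_intensities(self):
        with pytest.raises(ValidationError):
            CineLoop(frames=np.full((2, 4, 4), -0.1))

    def test_non_finite(self):
        frames = np.zeros((2, 4, 4))
        frames[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            CineLoop(frames=frames)


class TestWriteImage:
    def test_half_gray_rounds_up(self, tmp_path):
        """0.5 * 255 = 127.5 rounds away from zero to 128."""
        path = tmp_path / "half.png"
        write_image(np.full((5, 5), 0.5), path, bit_depth=8)
        import imageio.v2 as iio

        assert np.all(iio.imread(path) == 128)

    def test_zero_image(self, tmp_path):
        path = tmp_path / "zero.tif"
        write_image(np.zeros((5, 5)), path, bit_depth=16)
        assert np.all(tifffile.imread(path) == 0)

    @pytest.mark.parametrize("bit_depth", [8, 16])
    def test_quantization_bound(self, tmp_path, rng, bit_depth):
        img = rng.random((16, 16))
        path = tmp_path / "q.tif"
        write_image(img, path, bit_depth=bit_depth)
        back = read_image(path)
        bound = 1.0 / (2 * (2 ** bit_depth - 1))
        assert np.abs(back - img).max() <= bound + 1e-12

    def test_out_of_range_rejected(self, tmp_path):
        with pytest.raises(ValidationError, match="normalize"):
            write_image(np.full((4, 4), 1.5), tmp_path / "x.png")


class TestAnnotations:
    def test_points_roundtrip_full_precision(self, tmp_path):
        ann = PointAnnotation(
            points=[[0.123456789012, 5.0], [9.87654321, 3.3], [1.0, 1.0], [2.0, 7.5]],
            closed=True,
            label="cam_vessel",
        )
        path = tmp_path / "ann.json"
        write_annotations([ann], path)
        (back,) = read_annotations(path)
        assert isinstance(back, PointAnnotation)
        assert back.closed is True
        assert back.label == "cam_vessel"
        np.testing.assert_array_equal(back.points, ann.points)

    def test_single_pixel_mask_roundtrip(self, tmp_path):
        mask = np.zeros((4, 6), dtype=bool)
        mask[0, 0] = True
        path = tmp_path / "mask.json"
        write_annotations([RoiMask(mask=mask, label="microvessel")], path)
        (back,) = read_annotations(path)
        assert back.label == "microvessel"
        np.testing.assert_array_equal(back.mask, mask)

    def test_negative_point_rejected(self):
        with pytest.raises(ValidationError):
            PointAnnotation(points=[[-1.0, 5.0], [1.0, 1.0]], closed=False)

    def test_point_extent_check(self):
        ann = PointAnnotation(points=[[5.0, 5.0], [20.0, 5.0]], closed=False)
        with pytest.raises(ValidationError, match="extent"):
            ann.validate_extent((10, 10))

    def test_malformed_json_names_failing_field(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"items": [{"type": "mask", "shape": [2, 2]}]}))
        with pytest.raises(ValidationError, match="items\\[0\\]"):
            read_annotations(path)

    def test_closed_needs_three_points(self):
        with pytest.raises(ValidationError):
            PointAnnotation(points=[[0, 0], [1, 1]], closed=True)

    @given(
        st.lists(st.booleans(), min_size=1, max_size=200),
        st.integers(min_value=1, max_value=7),
    )
    def test_rle_roundtrip(self, bits, ncols):
        nrows = -(-len(bits) // ncols)
        mask = np.zeros(nrows * ncols, dtype=bool)
        mask[: len(bits)] = bits
        mask = mask.reshape(nrows, ncols)
        np.testing.assert_array_equal(rle_to_mask(mask_to_rle(mask), mask.shape), mask)
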