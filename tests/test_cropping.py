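import numpy as np
import pytest
from hypothesis import given, strategies as st

import petalseg as ps
from petalseg.cropping import CropFrame, footprint_pixels


CENTER = (79.5, 79.5)


def _frame(theta=0.0, length=120, width=16, center=CENTER):
    return CropFrame(center, theta, length, width)


class TestMakeCropFrames:
    @pytest.mark.parametrize("step,count", [(1.0, 360), (90.0, 4), (2.0, 180)])
    def test_counts(self, step, count):
        frames = ps.make_crop_frames(CENTER, 900, 32, step)
        assert len(frames) == count
        assert frames[0].theta_deg == 0.0
        assert frames[-1].theta_deg == pytest.approx(360.0 - step)

    def test_non_divisor_step_rejected(self):
        with pytest.raises(ValueError):
            ps.make_crop_frames(CENTER, 900, 32, 7.0)


class TestCoordinateContract:
    def test_central_pixel_maps_to_center(self):
        f = _frame(theta=33.0)
        row, col = ps.crop_to_slice(f, (f.length - 1) / 2.0, (f.width - 1) / 2.0)
        assert (row, col) == pytest.approx(CENTER)

    def test_theta_zero_long_axis_along_columns(self):
        f = _frame(theta=0.0)
        r0, c0 = ps.crop_to_slice(f, 0, (f.width - 1) / 2.0)
        r1, c1 = ps.crop_to_slice(f, f.length - 1, (f.width - 1) / 2.0)
        assert r0 == pytest.approx(r1)  # horizontal strip
        assert c1 - c0 == pytest.approx(f.length - 1)

    @given(st.floats(0, 359.999), st.floats(-50, 350), st.floats(-50, 350))
    def test_round_trip_is_algebraic_inverse(self, theta, row, col):
        f = _frame(theta=theta)
        u, v = ps.slice_to_crop(f, row, col)
        r2, c2 = ps.crop_to_slice(f, u, v)
        assert abs(r2 - row) < 1e-9 and abs(c2 - col) < 1e-9


class TestExtractCrop:
    def test_constant_image_inside(self):
        img = ps.SliceImage(np.full((160, 160), 50.0, dtype=np.float32), 1.0)
        crop = ps.extract_crop(img, _frame(theta=30.0), bg_mean=0.0)
        assert not crop.fill_mask.any()
        np.testing.assert_array_equal(crop.pixels, 50.0)

    def test_same_seed_bit_identical(self):
        img = ps.SliceImage(np.zeros((60, 60), dtype=np.float32), 1.0)
        f = CropFrame((29.5, 29.5), 45.0, 120, 8)
        a = ps.extract_crop(img, f, 10.0, 5.0, rng_seed=7)
        b = ps.extract_crop(img, f, 10.0, 5.0, rng_seed=7)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(a.fill_mask, b.fill_mask)

    def test_different_seeds_differ_only_on_fill(self):
        rng = np.random.default_rng(3)
        img = ps.SliceImage(rng.normal(40, 4, (60, 60)).astype(np.float32), 1.0)
        f = CropFrame((29.5, 29.5), 10.0, 120, 8)
        a = ps.extract_crop(img, f, 10.0, 5.0, rng_seed=1)
        b = ps.extract_crop(img, f, 10.0, 5.0, rng_seed=2)
        diff = a.pixels != b.pixels
        assert diff.any()
        assert not (diff & ~a.fill_mask).any()

    def test_vertical_strip_fill_rows_analytic(self):
        # 858-row image, 900-long vertical strip through the image center:
        # mapped rows are center_row + (u - 449.5); exactly 858 values of u
        # land inside [0, 858), the remaining 42 rows of the crop are fill.
        img = ps.SliceImage(np.zeros((858, 915), dtype=np.float32), 1.0)
        f = CropFrame((428.5, 457.0), 90.0, 900, 32)
        crop = ps.extract_crop(img, f, 0.0, 5.0, rng_seed=0)
        fill_rows = np.flatnonzero(crop.fill_mask.all(axis=1))
        assert crop.fill_mask.sum() == 42 * 32
        assert set(fill_rows) == set(range(21)) | set(range(879, 900))

    def test_rotation_consistency_theta_plus_180(self, small_phantom):
        vol, _ = small_phantom
        img = vol.slices[0]
        fa = CropFrame(CENTER, 25.0, 200, 24)
        fb = CropFrame(CENTER, 205.0, 200, 24)
        a = ps.extract_crop(img, fa, 20.0, 5.0, rng_seed=0)
        b = ps.extract_crop(img, fb, 20.0, 5.0, rng_seed=0)
        flipped = b.pixels[::-1, ::-1]
        flipped_fill = b.fill_mask[::-1, ::-1]
        ok = ~a.fill_mask & ~flipped_fill
        np.testing.assert_array_equal(a.pixels[ok], flipped[ok])

    def test_integer_dtype_fill_clamped(self):
        img = ps.SliceImage(np.zeros((40, 40), dtype=np.uint8), 1.0)
        f = CropFrame((19.5, 19.5), 0.0, 120, 4)
        crop = ps.extract_crop(img, f, 2.0, 100.0, rng_seed=5)
        assert crop.pixels.dtype == np.uint8  # draws clamped, no wraparound


class TestBackprojection:
    def test_all_true_mask_footprint_area(self):
        f = CropFrame((200.0, 200.0), 37.0, 300, 20)  # fully inside 400x400
        out = ps.backproject_mask(np.ones((300, 20), bool), f, (400, 400))
        area = out.sum()
        assert 300 * 20 * 0.95 <= area <= 300 * 20 * 1.05

    def test_all_false_mask(self):
        f = _frame()
        out = ps.backproject_mask(np.zeros((f.length, f.width), bool), f, (160, 160))
        assert not out.any()

    def test_footprints_symmetric_under_180(self):
        for shape in [(160, 160), (120, 150)]:
            fa = footprint_pixels(CropFrame(CENTER, 23.0, 200, 24), shape)
            fb = footprint_pixels(CropFrame(CENTER, 203.0, 200, 24), shape)
            np.testing.assert_array_equal(fa, fb)

    def test_width_one_frame_horizontal_is_single_row(self):
        f = CropFrame((10.0, 10.0), 0.0, 21, 1)
        out = ps.crop_footprint(f, (21, 21))
        rows = np.unique(np.nonzero(out)[0])
        assert list(rows) == [10]

    def test_adjacent_angle_footprints_overlap(self):
        # premise of the adjacent-pair integration: 1-degree neighbours share
        # most of their strip
        shape = (915, 858)
        fa = footprint_pixels(CropFrame((457.0, 428.5), 40.0, 900, 32), shape)
        fb = footprint_pixels(CropFrame((457.0, 428.5), 41.0, 900, 32), shape)
        inter = np.intersect1d(fa, fb, assume_unique=True).size
        assert inter / fa.size > 0.7

    def test_extract_backproject_reextract_agreement(self, small_phantom):
        vol, gt = small_phantom
        f = CropFrame(CENTER, 77.0, 260, 24)
        crop = ps.extract_crop(vol.slices[0], f, 20.0, 5.0, rng_seed=0)
        src = crop.src_flat
        gt_mask = (gt.masks[0].labels == 3).reshape(-1)
        m_crop = np.zeros(src.shape, bool)
        m_crop[src >= 0] = gt_mask[src[src >= 0]]
        m_slice = ps.backproject_mask(m_crop, f, vol.shape)
        m_crop2 = np.zeros(src.shape, bool)
        m_crop2[src >= 0] = m_slice.reshape(-1)[src[src >= 0]]
        ok = src >= 0
        agree = (m_crop[ok] == m_crop2[ok]).mean()
        assert agree >= 0.99
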