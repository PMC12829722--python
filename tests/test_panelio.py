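"""Frame I/O, marker-line detection, panel splitting and mask transfer."""

import numpy as np
import pytest
from PIL import Image

from eusei import panelio
from eusei.colorspace import rgb_to_hsv
from eusei.errors import GeometryError, InvalidArgumentError
from eusei.panelio import LesionMask, SplitGeometry
from eusei.phantom import PhantomTruth, make_phantom

from conftest import small_truth


class TestLoadFrame:
    def test_png_round_trip(self, tmp_path):
        img = np.random.default_rng(0).integers(0, 256, (30, 60, 3), dtype=np.uint8)
        path = tmp_path / "f.png"
        panelio.save_frame(img, path)
        loaded = panelio.load_frame(path)
        assert loaded.shape == (30, 60, 3)
        assert np.array_equal(loaded, img)

    def test_grayscale_promoted_to_rgb(self, tmp_path):
        gray = np.full((20, 20), 77, dtype=np.uint8)
        path = tmp_path / "g.png"
        Image.fromarray(gray, mode="L").save(path)
        loaded = panelio.load_frame(path)
        assert loaded.shape == (20, 20, 3)
        assert np.all(loaded == 77)

    def test_16bit_rescaled_linearly(self, tmp_path):
        arr = np.zeros((10, 10), dtype=np.uint16)
        arr[0, 0] = 65535
        arr[0, 1] = 32768
        path = tmp_path / "deep.png"
        Image.fromarray(arr).save(path)
        loaded = panelio.load_frame(path)
        assert loaded[0, 0, 0] == 255
        assert loaded[0, 1, 0] == 128
        assert loaded[5, 5, 0] == 0

    def test_truncated_file_raises_io_error(self, tmp_path):
        good = tmp_path / "ok.png"
        panelio.save_frame(np.zeros((50, 50, 3), dtype=np.uint8), good)
        blob = good.read_bytes()
        bad = tmp_path / "trunc.png"
        bad.write_bytes(blob[: len(blob) // 2])
        with pytest.raises(OSError):
            panelio.load_frame(bad)

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            panelio.load_frame(tmp_path / "absent.png")


class TestDetectMarkerLine:
    def test_recovers_phantom_marker_exactly(self):
        frame, _ = make_phantom(PhantomTruth(seed=3))
        geom = panelio.detect_marker_line(frame)
        assert geom.split_x == 298
        assert geom.marker_width == 4
        assert not geom.fallback

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_split_within_one_pixel_across_seeds(self, seed):
        truth = small_truth(seed=seed, e_star=0.2 + 0.05 * seed)
        frame, _ = make_phantom(truth)
        geom = panelio.detect_marker_line(frame)
        assert abs(geom.split_x - truth.split_x) <= 1

    def test_fixed_mode_returns_given_x(self):
        img = np.zeros((10, 600, 3), dtype=np.uint8)
        geom = panelio.detect_marker_line(img, mode="fixed", fixed_x=310)
        assert geom.split_x == 310

    def test_fixed_outside_central_band_rejected(self):
        img = np.zeros((10, 600, 3), dtype=np.uint8)
        with pytest.raises(InvalidArgumentError):
            panelio.detect_marker_line(img, mode="fixed", fixed_x=50)

    def test_uniform_image_falls_back_to_half_width(self):
        img = np.full((40, 600, 3), 90, dtype=np.uint8)
        geom = panelio.detect_marker_line(img)
        assert geom.fallback
        assert geom.split_x == 300


class TestSplitPanels:
    def test_equal_panels(self):
        img = np.zeros((300, 600, 3), dtype=np.uint8)
        left, right = panelio.split_panels(img, SplitGeometry(298, 4, 600))
        assert left.shape == (300, 298, 3)
        assert right.shape == (300, 298, 3)

    def test_empty_left_panel_rejected(self):
        img = np.zeros((10, 100, 3), dtype=np.uint8)
        with pytest.raises(GeometryError):
            panelio.split_panels(img, SplitGeometry(0, 4, 100))

    def test_narrow_right_panel_padded(self):
        img = np.full((10, 601, 3), 50, dtype=np.uint8)
        left, right = panelio.split_panels(img, SplitGeometry(300, 3, 601))
        assert left.shape == right.shape == (10, 300, 3)
        assert np.all(right[:, -2:] == 0)  # black padding at the right edge

    def test_large_mismatch_is_geometry_error(self):
        img = np.zeros((10, 600, 3), dtype=np.uint8)
        with pytest.raises(GeometryError):
            panelio.split_panels(img, SplitGeometry(200, 4, 600))

    def test_split_then_reassemble_is_identity(self):
        frame, _ = make_phantom(PhantomTruth(seed=9))
        geom = panelio.detect_marker_line(frame)
        left, right = panelio.split_panels(frame, geom)
        marker = frame[:, geom.split_x : geom.split_x + geom.marker_width]
        rebuilt = np.concatenate([left, marker, right], axis=1)
        assert np.array_equal(rebuilt, frame)


class TestMaskTransfer:
    def test_identity_in_panel_local_coordinates(self):
        bits = np.zeros((300, 298), dtype=bool)
        bits[140:160, 90:110] = True
        mask = LesionMask(bits=bits, panel_side="left")
        moved = panelio.map_mask_to_elasto(mask, SplitGeometry(298, 4, 600))
        assert moved.panel_side == "right"
        assert np.array_equal(moved.bits, bits)
        assert moved.count == mask.count

    def test_full_panel_mask_preserved(self):
        mask = LesionMask(bits=np.ones((300, 298), dtype=bool))
        moved = panelio.map_mask_to_elasto(mask, SplitGeometry(298, 4, 600))
        assert moved.count == 300 * 298

    def test_dimension_mismatch_rejected(self):
        mask = LesionMask(bits=np.ones((300, 200), dtype=bool))
        with pytest.raises(GeometryError):
            panelio.map_mask_to_elasto(mask, SplitGeometry(298, 4, 600))

    def test_mapped_mask_overlaps_painted_lesion_perfectly(self):
        # stiff lesion (blue) vs green background: the painted region in the
        # elastogram panel must coincide with the transferred mask (Dice 1)
        truth = small_truth(e_star=0.0, hue_noise_sd=0.0, seed=5)
        frame, mask = make_phantom(truth)
        geom = panelio.detect_marker_line(frame)
        _, elasto = panelio.split_panels(frame, geom)
        moved = panelio.map_mask_to_elasto(mask, geom)
        hsv = rgb_to_hsv(elasto.astype(float))
        painted = hsv[:, :, 0] > 200  # blue region
        inter = np.logical_and(painted, moved.bits).sum()
        dice = 2 * inter / (painted.sum() + moved.count)
        assert dice == pytest.approx(1.0)


class TestMaskIO:
    def _mask(self):
        bits = np.zeros((40, 30), dtype=bool)
        bits[10:25, 5:20] = True
        bits[12, 8] = False
        return LesionMask(bits=bits, panel_side="left")

    def test_png_round_trip(self, tmp_path):
        mask = self._mask()
        path = tmp_path / "m.png"
        panelio.save_mask_png(mask, path)
        loaded = panelio.load_mask(path)
        assert np.array_equal(loaded.bits, mask.bits)

    def test_json_rle_round_trip(self, tmp_path):
        mask = self._mask()
        path = tmp_path / "m.json"
        panelio.save_mask_json(mask, path)
        loaded = panelio.load_mask(path)
        assert np.array_equal(loaded.bits, mask.bits)
        assert loaded.panel_side == "left"
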