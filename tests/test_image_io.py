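import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neuromorph import GrayImage, ValidationError, read_image, read_mask, write_csv, write_image, write_mask
from neuromorph.io import read_csv, read_manifest
from neuromorph.synthetic import SceneSpec, generate_scene


class TestReadWriteImage:
    def test_constant_png_round_trip(self, tmp_path):
        img = GrayImage(np.full((64, 64), 7, dtype=np.int64), bit_depth=8)
        back = read_image(write_image(img, tmp_path / "c.png"))
        assert back.bit_depth == 8
        assert np.array_equal(back.pixels, img.pixels)

    def test_16bit_tiff_round_trip_from_generator(self, tmp_path):
        img, _ = generate_scene(
            SceneSpec(shape=(96, 96), n_somata=3, n_neurites_per_soma=(0, 0),
                      bit_depth=16, foreground=48000, background=6000, seed=4)
        )
        back = read_image(write_image(img, tmp_path / "s.tif"))
        assert back.bit_depth == 16
        assert np.array_equal(back.pixels, img.pixels)

    def test_truncated_file_raises_io_error(self, tmp_path):
        path = tmp_path / "broken.tif"
        path.write_bytes(b"II*\x00trunc")
        with pytest.raises(OSError):
            read_image(path)

    def test_rgb_png_converts_to_luminance(self, tmp_path):
        import imageio.v3 as iio

        rgb = np.zeros((8, 8, 3), np.uint8)
        rgb[..., 0] = 100  # pure red: luminance 0.299*100 = 30
        iio.imwrite(tmp_path / "rgb.png", rgb)
        img = read_image(tmp_path / "rgb.png")
        assert img.pixels.shape == (8, 8)
        assert np.all(img.pixels == 30)

    def test_invalid_images_rejected(self):
        with pytest.raises(ValidationError):
            GrayImage(np.zeros((0, 4), np.int64))
        with pytest.raises(ValidationError):
            GrayImage(np.full((4, 4), 300, np.int64), bit_depth=8)


class TestReadMask:
    def test_polarity_and_involution(self, tmp_path):
        arr = (np.arange(36).reshape(6, 6) % 2 * 255).astype(np.int64)
        write_image(GrayImage(arr), tmp_path / "m.png")
        white = read_mask(tmp_path / "m.png", foreground="white")
        black = read_mask(tmp_path / "m.png", foreground="black")
        assert np.array_equal(white, arr == 255)
        assert np.array_equal(black, ~white)

    def test_write_mask_round_trip(self, tmp_path):
        mask = np.random.default_rng(1).random((10, 10)) > 0.5
        write_mask(mask, tmp_path / "m.tif")
        assert np.array_equal(read_mask(tmp_path / "m.tif"), mask)

    def test_multilevel_image_rejected_with_count(self, tmp_path):
        arr = (np.arange(25).reshape(5, 5) % 5 * 60).astype(np.int64)
        write_image(GrayImage(arr), tmp_path / "m.png")
        with pytest.raises(ValidationError, match="5 distinct"):
            read_mask(tmp_path / "m.png")


class TestCsv:
    def test_header_plus_rows(self, tmp_path):
        rows = [{"a": 1, "b": 2.5}, {"a": 2, "b": 3.5}, {"a": 3, "b": 4.5}]
        path = write_csv(rows, tmp_path / "t.csv")
        assert len(path.read_text().strip().splitlines()) == 4

    def test_empty_table_is_header_only(self, tmp_path):
        path = write_csv(pd.DataFrame(columns=["a", "b"]), tmp_path / "e.csv")
        assert path.read_text().strip() == "a,b"

    def test_round_trip_to_nine_significant_digits(self, tmp_path):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.normal(size=20) * 1e3, "y": rng.random(20)})
        back = read_csv(write_csv(df, tmp_path / "r.csv"))
        assert np.allclose(back["x"], df["x"], rtol=1e-9)
        assert np.allclose(back["y"], df["y"], rtol=1e-9)


class TestManifest:
    def _write(self, tmp_path, rows):
        df = pd.DataFrame(rows)
        path = tmp_path / "manifest.csv"
        df.to_csv(path, index=False)
        return path

    def test_load_and_image_ids(self, tmp_path):
        (tmp_path / "a.tif").touch()
        path = self._write(
            tmp_path,
            [{"path": "a.tif", "well_id": "W1", "area_id": "A1", "time_h": 0.0, "condition": "ctrl"}],
        )
        m = read_manifest(path)
        assert m.image_ids == ["a"]

    def test_missing_file_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            [{"path": "gone.tif", "well_id": "W1", "area_id": "A1", "time_h": 0.0, "condition": "c"}],
        )
        with pytest.raises(ValidationError, match="missing files"):
            read_manifest(path)

    def test_duplicate_paths_and_negative_time_rejected(self, tmp_path):
        (tmp_path / "a.tif").touch()
        row = {"path": "a.tif", "well_id": "W1", "area_id": "A1", "time_h": 0.0, "condition": "c"}
        with pytest.raises(ValidationError, match="not unique"):
            read_manifest(self._write(tmp_path, [row, row]))
        bad = dict(row, time_h=-1.0)
        with pytest.raises(ValidationError, match="time_h"):
            read_manifest(self._write(tmp_path, [bad]))


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_mask_polarity_involution_property(tmp_path_factory, seed):
    """Reading with the opposite foreground flag yields the exact complement."""
    tmp = tmp_path_factory.mktemp("inv")
    rng = np.random.default_rng(seed)
    arr = np.where(rng.random((7, 9)) > 0.5, 255, 0).astype(np.int64)
    write_image(GrayImage(arr), tmp / "m.png")
    if len(np.unique(arr)) < 2:  # degenerate all-one-level draw
        return
    assert np.array_equal(
        read_mask(tmp / "m.png", "white"), ~read_mask(tmp / "m.png", "black")
    )
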