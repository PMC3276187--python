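"""Frame indexing, day/night separation and cropping to per-plant stacks."""

from datetime import datetime

import numpy as np
import pytest
from PIL import Image

from rosettrack.image_io import (
    CoordinateMap,
    PotEntry,
    build_flat_index,
    classify_day_night,
    crop_to_stacks,
    load_flat_image,
    mean_filtered_intensity,
    read_coordinate_maps,
    suggest_cutoff,
)

T0 = datetime(2021, 4, 1, 8, 0, 0)


def _touch_frames(d, names):
    for n in names:
        (d / n).write_bytes(b"")


class TestBuildFlatIndex:
    def test_corrupt_excluded_and_sorted(self, tmp_path):
        names = [f"flat_202104{d:02d}-120000.jpg" for d in range(1, 11)]
        _touch_frames(tmp_path, names)
        corrupt = {names[2], names[7]}
        idx = build_flat_index(tmp_path, datetime(2021, 4, 1), datetime(2021, 5, 1),
                               corrupt_list=corrupt)
        assert len(idx) == 8
        assert [n for n, _ in idx] == sorted(set(names) - corrupt)
        # independent sort oracle: times ascending
        times = [t for _, t in idx]
        assert times == sorted(times)

    def test_window_excludes_outside_frames(self, tmp_path):
        names = [f"f_202104{d:02d}-090000.jpg" for d in (1, 5, 9, 20)]
        _touch_frames(tmp_path, names)
        idx = build_flat_index(tmp_path, datetime(2021, 4, 4), datetime(2021, 4, 10))
        assert [n for n, _ in idx] == names[1:3]

    def test_unparseable_warned_and_excluded(self, tmp_path):
        _touch_frames(tmp_path, ["f_20210401-090000.jpg", "nodate.jpg"])
        with pytest.warns(UserWarning, match="nodate"):
            idx = build_flat_index(tmp_path, datetime(2021, 1, 1), datetime(2022, 1, 1))
        assert len(idx) == 1

    def test_empty_result_is_error(self, tmp_path):
        _touch_frames(tmp_path, ["f_20210401-090000.jpg"])
        with pytest.raises(ValueError):
            build_flat_index(tmp_path, datetime(2022, 1, 1), datetime(2022, 2, 1))

    def test_inverted_window_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            build_flat_index(tmp_path, datetime(2022, 2, 1), datetime(2022, 1, 1))


class TestMeanFilteredIntensity:
    def test_examples(self):
        img = np.zeros((4, 4, 3))
        img[..., 0] = img[..., 1] = 0.5
        assert mean_filtered_intensity(img) == pytest.approx(0.0)
        img[..., 1] = 0.8
        img[..., 0] = 0.3
        assert mean_filtered_intensity(img) == pytest.approx(0.5)
        # checkerboard: half (G-R)=0.4, half 0
        img = np.zeros((2, 2, 3))
        img[0, 0, 1] = img[1, 1, 1] = 0.4
        assert mean_filtered_intensity(img) == pytest.approx(0.2)


class TestDayNight:
    def test_bimodal_series_classified_correctly(self):
        rng = np.random.default_rng(0)
        night = rng.normal(0.01, 0.002, 20)
        day = rng.normal(0.3, 0.02, 30)
        values = np.concatenate([night, day])
        truth = ["night"] * 20 + ["day"] * 30
        series = [(T0, float(v)) for v in values]
        assert classify_day_night(series, 0.1) == truth
        cut = suggest_cutoff(values)
        assert classify_day_night(series, cut) == truth

    def test_cutoff_below_minimum_labels_all_day(self):
        series = [(T0, v) for v in (0.2, 0.3, 0.4)]
        assert classify_day_night(series, 0.1) == ["day"] * 3

    def test_constant_series_has_no_suggestion(self):
        with pytest.raises(ValueError, match="no bimodality"):
            suggest_cutoff([0.2] * 10)

    def test_monotone_thresholding(self):
        values = [0.05, 0.15, 0.25, 0.35]
        series = [(T0, v) for v in values]
        lo = classify_day_night(series, 0.0)
        hi = classify_day_night(series, 0.2)
        flipped = [v for v, a, b in zip(values, lo, hi) if a != b]
        assert all(0.0 < v <= 0.2 for v in flipped)


def _write_flat(path, value_grid):
    """A flat image whose pixel values encode position (for crop identity)."""
    arr = np.zeros((64, 96, 3), dtype=np.uint8)
    arr[..., 0] = value_grid
    arr[..., 1] = 128
    Image.fromarray(arr).save(path)
    return arr


class TestCropToStacks:
    def _scene(self, tmp_path, n_days=2, frames_per_day=3):
        yy, xx = np.mgrid[:64, :96]
        grid = ((yy * 2 + xx // 2) % 255).astype(np.uint8)
        names, labels = [], []
        for d in range(n_days):
            for j in range(frames_per_day):
                name = f"f_202104{d + 1:02d}-{9 + j:02d}0000.jpg"
                _write_flat(tmp_path / name.replace(".jpg", ".png"), grid)
                (tmp_path / name.replace(".jpg", ".png")).rename(tmp_path / name.replace(".jpg", ".png"))
                names.append(name.replace(".jpg", ".png"))
        idx = build_flat_index(tmp_path, datetime(2021, 3, 1), datetime(2021, 5, 1))
        return idx, grid

    def test_single_pot_stack(self, tmp_path):
        idx, grid = self._scene(tmp_path)
        pot = PotEntry("p1", 48, 32, 20, 16, "accA")
        cmap = CoordinateMap("flat", datetime(2021, 1, 1), [pot])
        labels = ["day"] * len(idx)
        stacks = crop_to_stacks(idx, [cmap], labels, tmp_path)
        assert len(stacks) == 1
        st = stacks[0]
        assert len(st.frames) == len(idx)
        assert st.frames[0].pixels.shape == (16, 20, 3)
        assert [f.day_index for f in st.frames] == [1, 1, 1, 2, 2, 2]
        assert [f.within_day_index for f in st.frames] == [1, 2, 3, 1, 2, 3]
        # pixel identity against a manual crop (box [c - w/2, c + w/2))
        manual = grid[32 - 8: 32 + 8, 48 - 10: 48 + 10] / 255.0
        np.testing.assert_allclose(st.frames[0].pixels[..., 0], manual)

    def test_night_frames_excluded(self, tmp_path):
        idx, _ = self._scene(tmp_path)
        pot = PotEntry("p1", 48, 32, 20, 16, "accA")
        cmap = CoordinateMap("flat", datetime(2021, 1, 1), [pot])
        labels = ["day", "night", "day"] * 2
        stacks = crop_to_stacks(idx, [cmap], labels, tmp_path)
        assert len(stacks[0].frames) == 4  # conservation: exactly the day frames

    def test_map_switch_mid_series(self, tmp_path):
        idx, grid = self._scene(tmp_path)
        m1 = CoordinateMap("flat", datetime(2021, 1, 1),
                           [PotEntry("p1", 48, 32, 20, 16, "accA")])
        m2 = CoordinateMap("flat", datetime(2021, 4, 2),
                           [PotEntry("p1", 50, 34, 20, 16, "accA")])
        stacks = crop_to_stacks(idx, [m1, m2], ["day"] * len(idx), tmp_path)
        st = stacks[0]
        before = grid[32 - 8: 32 + 8, 48 - 10: 48 + 10] / 255.0
        after = grid[34 - 8: 34 + 8, 50 - 10: 50 + 10] / 255.0
        np.testing.assert_allclose(st.frames[0].pixels[..., 0], before)
        np.testing.assert_allclose(st.frames[-1].pixels[..., 0], after)

    def test_uncovered_frame_is_error(self, tmp_path):
        idx, _ = self._scene(tmp_path)
        late = CoordinateMap("flat", datetime(2021, 4, 2),
                             [PotEntry("p1", 48, 32, 20, 16, "accA")])
        with pytest.raises(ValueError, match="2021-04-01"):
            crop_to_stacks(idx, [late], ["day"] * len(idx), tmp_path)

    def test_out_of_bounds_box_is_error(self, tmp_path):
        idx, _ = self._scene(tmp_path)
        bad = CoordinateMap("flat", datetime(2021, 1, 1),
                            [PotEntry("edge", 90, 32, 20, 16, "accA")])
        with pytest.raises(ValueError, match="edge"):
            crop_to_stacks(idx, [bad], ["day"] * len(idx), tmp_path)


def test_coordinate_map_round_trip(tmp_path):
    csv = tmp_path / "coords.csv"
    csv.write_text(
        "flat_id,valid_from,pot_id,center_x,center_y,crop_w,crop_h,accession\n"
        "flat01,2021-04-01T00:00:00,r0c0,32,32,64,64,accA\n"
        "flat01,2021-04-01T00:00:00,r0c1,96,32,64,64,accB\n"
        "flat01,2021-04-05T00:00:00,r0c0,34,32,64,64,accA\n"
        "flat01,2021-04-05T00:00:00,r0c1,98,32,64,64,accB\n"
    )
    maps = read_coordinate_maps(csv)
    assert [m.valid_from.day for m in maps] == [1, 5]
    assert [p.pot_id for p in maps[0].pots] == ["r0c0", "r0c1"]
    assert maps[1].pots[0].center_x == 34


def test_duplicate_pot_ids_rejected():
    pots = [PotEntry("p1", 10, 10, 8, 8, "a"), PotEntry("p1", 30, 10, 8, 8, "b")]
    with pytest.raises(ValueError):
        CoordinateMap("flat", datetime(2021, 1, 1), pots)


def test_load_flat_image_scales_to_unit_interval(tmp_path):
    arr = np.full((8, 8, 3), 255, dtype=np.uint8)
    Image.fromarray(arr).save(tmp_path / "f.png")
    img = load_flat_image(tmp_path / "f.png", T0)
    assert img.pixels.max() == pytest.approx(1.0)
    assert img.pixels.min() == pytest.approx(1.0)
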