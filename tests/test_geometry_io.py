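"""Screen geometry conversion and file-format round trips."""

import math

import numpy as np
import pandas as pd
import pytest

import gazefield as gf
from gazefield.io_formats import (DataError, EventTableDialect, FormatError,
                                  read_event_table, read_map,
                                  read_sensitivity_grid, write_map,
                                  write_sensitivity_grid)
from gazefield.maps import MapSpec, VFMap
from gazefield.perimetry import hfa_locations


class TestScreenGeometry:
    def test_screen_center_maps_to_origin(self, geometry):
        x, y = geometry.px_to_deg(960, 540)
        assert x == pytest.approx(0.0, abs=1e-12)
        assert y == pytest.approx(0.0, abs=1e-12)

    def test_one_degree_pixel_offset_matches_trig_oracle(self, geometry):
        # hand-computed: one degree rightward = tan(1 deg)*60 cm on screen,
        # at 50/1920 cm per pixel
        px_per_deg = math.tan(math.radians(1.0)) * 60.0 / (50.0 / 1920.0)
        x, y = geometry.px_to_deg(960 + px_per_deg, 540)
        assert x == pytest.approx(1.0, abs=1e-6)
        assert y == pytest.approx(0.0, abs=1e-9)

    def test_printed_subtense(self, geometry):
        w, h = geometry.subtense_deg
        assert w == pytest.approx(45.2, abs=0.05)
        assert h == pytest.approx(32.5, abs=0.05)

    def test_conversion_invertible_everywhere(self, geometry):
        gx, gy = np.meshgrid(np.linspace(-22, 22, 23), np.linspace(-16, 16, 17))
        px, py = geometry.deg_to_px(gx.ravel(), gy.ravel())
        bx, by = geometry.px_to_deg(px, py)
        assert np.abs(bx - gx.ravel()).max() < 1e-9
        assert np.abs(by - gy.ravel()).max() < 1e-9

    def test_y_axis_points_up(self, geometry):
        _, y = geometry.px_to_deg(960, 0)  # top of screen
        assert y > 0

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            gf.ScreenGeometry(0, 1080, 50, 35, 60)


def _events_csv(tmp_path, rows):
    cols = ["participant", "clip", "event", "t_on_ms", "t_off_ms",
            "x", "y", "x0", "y0", "x1", "y1", "amp_deg", "dir_deg", "pvel"]
    df = pd.DataFrame(rows, columns=cols)
    path = tmp_path / "events.csv"
    df.to_csv(path, index=False)
    return path


class TestEventTable:
    def test_fixation_at_screen_center(self, tmp_path, geometry):
        path = _events_csv(tmp_path, [
            ["p1", "c1", "fix", 0, 200, 960, 540, "", "", "", "", "", "", ""],
        ])
        trials = read_event_table(path, EventTableDialect(), geometry)
        assert len(trials) == 1
        f = trials[0].fixations[0]
        assert (f.x, f.y) == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_groups_by_participant_and_clip(self, tmp_path, geometry):
        path = _events_csv(tmp_path, [
            ["p1", "c1", "fix", 0, 200, 960, 540] + [""] * 7,
            ["p1", "c2", "fix", 0, 200, 960, 540] + [""] * 7,
            ["p2", "c1", "fix", 0, 200, 100, 100] + [""] * 7,
        ])
        trials = read_event_table(path, EventTableDialect(), geometry)
        assert {(t.participant, t.clip) for t in trials} == {
            ("p1", "c1"), ("p1", "c2"), ("p2", "c1")}

    def test_non_monotone_timestamps_name_the_trial(self, tmp_path, geometry):
        path = _events_csv(tmp_path, [
            ["p1", "c1", "fix", 500, 700, 960, 540] + [""] * 7,
            ["p1", "c1", "fix", 0, 200, 960, 540] + [""] * 7,
        ])
        with pytest.raises(DataError, match="p1"):
            read_event_table(path, EventTableDialect(), geometry)

    def test_missing_column_is_format_error(self, tmp_path, geometry):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"participant": ["p"], "clip": ["c"]}).to_csv(path, index=False)
        with pytest.raises(FormatError):
            read_event_table(path, EventTableDialect(), geometry)

    def test_reading_twice_is_identical(self, tmp_path, geometry):
        path = _events_csv(tmp_path, [
            ["p1", "c1", "fix", 0, 200, 800, 500] + [""] * 7,
            ["p1", "c1", "sac", 200, 230, "", "", 800, 500, 900, 450, "", "", 300],
        ])
        t1 = read_event_table(path, EventTableDialect(), geometry)
        t2 = read_event_table(path, EventTableDialect(), geometry)
        assert [f.position for t in t1 for f in t.fixations] == \
               [f.position for t in t2 for f in t.fixations]
        assert [s.amplitude for t in t1 for s in t.saccades] == \
               [s.amplitude for t in t2 for s in t.saccades]

    def test_event_table_round_trip(self, tmp_path, geometry, control_trial):
        from gazefield.io_formats import write_event_table
        path = tmp_path / "rt.csv"
        write_event_table([control_trial], path, geometry)
        back = read_event_table(path, EventTableDialect(), geometry)
        assert len(back) == 1
        orig = control_trial.fixation_positions()
        new = back[0].fixation_positions()
        assert np.abs(orig - new).max() < 1e-9


class TestIoConfig:
    def test_yaml_geometry_and_dialect(self, tmp_path):
        from gazefield.io_formats import load_io_config
        cfg = tmp_path / "io.yaml"
        cfg.write_text(
            "geometry: {width_px: 1920, height_px: 1080, width_cm: 50,"
            " height_cm: 35, distance_cm: 60}\n"
            "dialect: {kind: csv_events, columns: {participant: subj}}\n")
        geometry, dialect = load_io_config(cfg)
        assert geometry.subtense_deg[0] == pytest.approx(45.2, abs=0.05)
        assert dialect.resolve("participant") == "subj"
        assert dialect.resolve("clip") == "clip"

    def test_missing_geometry_block_rejected(self, tmp_path):
        from gazefield.io_formats import FormatError, load_io_config
        cfg = tmp_path / "io.yaml"
        cfg.write_text("dialect: {kind: csv_events}\n")
        with pytest.raises(FormatError):
            load_io_config(cfg)


ASC_SAMPLE = """\
MSG 100 TRIALID p1 c1
EFIX L 100 400 300 960.0 540.0 500
ESACC L 400 430 30 960.0 540.0 1100.0 500.0 3.5 250
EFIX L 430 800 370 1100.0 500.0 480
"""


class TestAscDialect:
    def test_efix_esacc_parsed_with_times_preserved(self, tmp_path, geometry):
        path = tmp_path / "rec.asc"
        path.write_text(ASC_SAMPLE)
        trials = read_event_table(path, EventTableDialect(kind="eyelink_asc"),
                                  geometry)
        assert len(trials) == 1
        t = trials[0]
        assert len(t.fixations) == 2 and len(t.saccades) == 1
        assert t.fixations[0].onset == 100 and t.fixations[0].offset == 400
        assert t.saccades[0].onset == 400 and t.saccades[0].offset == 430
        assert t.fixations[0].position == pytest.approx((0.0, 0.0), abs=1e-9)


class TestSensitivityGrid:
    def _grid_csv(self, tmp_path, layout, values=None, mirror_x=False):
        locs = hfa_locations(layout)
        if mirror_x:
            locs = locs.copy()
            locs[:, 0] *= -1
        values = np.full(len(locs), 28.0) if values is None else values
        path = tmp_path / f"{layout}.csv"
        pd.DataFrame({"location_id": range(len(locs)), "x_deg": locs[:, 0],
                      "y_deg": locs[:, 1], "sensitivity_db": values}
                     ).to_csv(path, index=False)
        return path

    def test_24_2_has_52_scored_locations(self, tmp_path):
        fld = read_sensitivity_grid(self._grid_csv(tmp_path, "hfa24_2"), "hfa24_2")
        assert len(fld.sensitivity) == 54
        assert fld.n_scored == 52

    def test_30_2_accepts_76_locations(self, tmp_path):
        fld = read_sensitivity_grid(self._grid_csv(tmp_path, "hfa30_2"), "hfa30_2")
        assert len(fld.sensitivity) == 76

    def test_count_mismatch_is_format_error(self, tmp_path):
        path = self._grid_csv(tmp_path, "hfa24_2")
        with pytest.raises(FormatError, match="76"):
            read_sensitivity_grid(path, "hfa30_2")

    def test_left_eye_mirrored_to_right_orientation(self, tmp_path):
        locs = hfa_locations("hfa24_2")
        vals = np.where(locs[:, 0] > 0, 30.0, 10.0)  # right half bright
        # store as a left-eye chart (x flipped)
        path = self._grid_csv(tmp_path, "hfa24_2", values=vals, mirror_x=True)
        fld = read_sensitivity_grid(path, "hfa24_2", eye="left")
        # mirroring restores each value to its canonical right-eye position
        assert np.allclose(fld.locations, locs)
        assert np.array_equal(fld.sensitivity, vals)

    def test_grid_round_trip(self, tmp_path):
        fld = gf.make_field("peripheral", 0.7, seed=5)
        path = tmp_path / "fld.csv"
        write_sensitivity_grid(fld, path)
        back = read_sensitivity_grid(path, "hfa24_2", md=fld.md)
        assert np.abs(back.sensitivity - fld.sensitivity).max() < 1e-9


class TestMapRoundTrip:
    def test_values_mask_and_metadata_survive(self, tmp_path):
        spec = MapSpec(half_x=21, half_y=11, bin_size=2)
        rng = np.random.default_rng(0)
        values = rng.normal(size=spec.shape)
        mask = rng.random(spec.shape) < 0.2
        values[mask] = 0.0
        m = VFMap(values=values, spec=spec, kind="rank", mask=mask,
                  provenance={"participant": "p1"})
        write_map(m, tmp_path / "m.tsv")
        back = read_map(tmp_path / "m.tsv")
        assert np.abs(back.values - m.values).max() < 1e-12
        assert np.array_equal(back.mask, m.mask)
        assert back.spec == m.spec
        assert back.kind == "rank"
        assert back.provenance["participant"] == "p1"

    def test_file_shape_matches_grid(self, tmp_path):
        spec = MapSpec(half_x=21, half_y=11, bin_size=2)  # 11 x 21 bins
        m = VFMap(values=np.zeros(spec.shape), spec=spec, kind="density")
        write_map(m, tmp_path / "m.tsv")
        raw = np.loadtxt(tmp_path / "m.tsv", delimiter="\t")
        assert raw.shape == (11, 21)
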