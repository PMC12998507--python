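"""Active-fire rasterization, Voronoi dating, appending and relocation."""

import numpy as np
import pandas as pd
import pytest

from peatfire import active_fire as af
from peatfire.raster import GridSpec

GRID = GridSpec(32, 32, 30.0)


def records(rows):
    return pd.DataFrame(rows, columns=["x", "y", "day", "year",
                                       "along_track_m", "cross_track_m"])


class TestRasterize:
    def test_375m_footprint_paints_13x13_block(self):
        # record centered on a pixel center: 375/30 = 12.5 -> 13 pixels
        rec = records([[15.5 * 30, 15.5 * 30, 180, 2015, 375.0, 375.0]])
        out = af.rasterize_active_fires(rec, GRID)
        rr, cc = np.nonzero(np.isfinite(out))
        assert rr.min() == 9 and rr.max() == 21
        assert cc.min() == 9 and cc.max() == 21
        assert np.isfinite(out).sum() == 13 * 13

    def test_coverage_matches_brute_force(self, rng):
        recs = records([[rng.uniform(100, 800), rng.uniform(100, 800),
                         int(rng.integers(100, 300)), 2015,
                         float(rng.choice([375.0, 1000.0])),
                         float(rng.choice([375.0, 1000.0]))]
                        for _ in range(10)])
        out = af.rasterize_active_fires(recs, GRID)
        # oracle: pixel covered iff center inside some rectangle; earliest day
        expect = np.full(GRID.shape, np.inf)
        for r in recs.itertuples():
            for i in range(GRID.height):
                for j in range(GRID.width):
                    cx, cy = (j + 0.5) * 30, (i + 0.5) * 30
                    if (abs(cx - r.x) <= r.along_track_m / 2
                            and abs(cy - r.y) <= r.cross_track_m / 2):
                        expect[i, j] = min(expect[i, j], r.day)
        expect[np.isinf(expect)] = np.nan
        np.testing.assert_array_equal(np.isnan(out), np.isnan(expect))
        ok = np.isfinite(out)
        np.testing.assert_array_equal(out[ok], expect[ok])

    def test_overlap_keeps_earliest_day(self):
        recs = records([[300, 300, 190, 2015, 375, 375],
                        [300, 300, 180, 2015, 375, 375]])
        out = af.rasterize_active_fires(recs, GRID)
        assert np.nanmin(out) == 180
        assert np.nanmax(out) == 180

    def test_empty_records_empty_raster(self):
        out = af.rasterize_active_fires(records([]), GRID)
        assert np.isnan(out).all()

    def test_out_of_bounds_skipped_with_warning(self):
        recs = records([[1e6, 1e6, 100, 2015, 375, 375]])
        with pytest.warns(UserWarning):
            out = af.rasterize_active_fires(recs, GRID)
        assert np.isnan(out).all()


class TestVoronoiDates:
    def burned_all(self):
        return np.ones(GRID.shape, dtype=bool)

    def test_nearest_record_wins(self):
        recs = records([[100, 100, 180, 2015, 375, 375],
                        [900, 900, 200, 2015, 375, 375]])
        burned = np.zeros(GRID.shape, dtype=bool)
        burned[3, 3] = True  # center (105, 105): ~7 m vs ~1.1 km
        day, conf = af.assign_dates_voronoi(burned, recs, GRID)
        assert day[3, 3] == 180 and conf[3, 3]

    def test_equidistant_tie_takes_earlier_day(self):
        burned = np.zeros(GRID.shape, dtype=bool)
        burned[0, 5] = True  # center x=165
        recs = records([[165 - 90, 15, 160, 2015, 375, 375],
                        [165 + 90, 15, 150, 2015, 375, 375]])
        day, _ = af.assign_dates_voronoi(burned, recs, GRID)
        assert day[0, 5] == 150

    def test_single_record_dates_everything(self):
        recs = records([[500, 500, 211, 2015, 375, 375]])
        day, conf = af.assign_dates_voronoi(self.burned_all(), recs, GRID)
        assert (day[conf] == 211).all() and conf.all()

    def test_no_records_keeps_fallback_flagged_low_confidence(self):
        fallback = np.full(GRID.shape, 140.0)
        day, conf = af.assign_dates_voronoi(
            self.burned_all(), records([]), GRID, fallback_day=fallback)
        assert (day == 140).all()
        assert not conf.any()

    def test_matches_brute_force_nearest_search(self, rng):
        recs = records([[rng.uniform(0, 960), rng.uniform(0, 960),
                         int(rng.integers(100, 300)), 2015, 375, 375]
                        for _ in range(12)])
        burned = rng.uniform(size=GRID.shape) < 0.3
        day, _ = af.assign_dates_voronoi(burned, recs, GRID)
        pts = recs[["x", "y"]].to_numpy()
        days = recs["day"].to_numpy()
        for i, j in zip(*np.nonzero(burned)):
            d = np.hypot(pts[:, 0] - (j + 0.5) * 30, pts[:, 1] - (i + 0.5) * 30)
            best = d.min()
            expect = days[d <= best + 1e-6].min()
            assert day[i, j] == expect


class TestAppend:
    def setup_mask(self):
        burned = np.zeros(GRID.shape, dtype=bool)
        burned[10, 10] = True
        af_day = np.full(GRID.shape, np.nan)
        water = np.zeros(GRID.shape)
        return burned, af_day, water

    def test_diagonal_af_pixel_appended(self):
        burned, af_day, water = self.setup_mask()
        af_day[11, 11] = 200
        water[11, 11] = 0.3
        out = af.append_af_pixels(burned, af_day, water)
        assert out[11, 11]

    def test_water_dominated_pixel_not_appended(self):
        burned, af_day, water = self.setup_mask()
        af_day[10, 11] = 200
        water[10, 11] = 0.85
        out = af.append_af_pixels(burned, af_day, water)
        assert not out[10, 11]

    def test_isolated_af_pixel_not_appended(self):
        burned, af_day, water = self.setup_mask()
        af_day[20, 20] = 200
        out = af.append_af_pixels(burned, af_day, water)
        assert not out[20, 20]

    def test_chains_attach_iteratively(self):
        burned, af_day, water = self.setup_mask()
        for k in range(1, 6):
            af_day[10, 10 + k] = 200
        out = af.append_af_pixels(burned, af_day, water)
        assert out[10, 11:16].all()

    def test_output_is_superset_of_input(self, rng):
        burned = rng.uniform(size=GRID.shape) < 0.2
        af_day = np.where(rng.uniform(size=GRID.shape) < 0.3, 200.0, np.nan)
        water = rng.uniform(size=GRID.shape)
        out = af.append_af_pixels(burned, af_day, water)
        assert (out | burned).sum() == out.sum()
        assert (out & burned).sum() == burned.sum()


class TestRelocateYear:
    def one_burned_pixel(self):
        burned = np.zeros(GRID.shape, dtype=bool)
        burned[0, 0] = True  # center (15, 15)
        return burned

    def rec_at(self, dist_m, day=200, year=2015):
        return records([[15.0 + dist_m, 15.0, day, year, 375, 375]])

    def test_both_conditions_met_relocates(self):
        move = af.relocate_year(self.one_burned_pixel(),
                                self.rec_at(3000, year=2014),
                                self.rec_at(7000), GRID)
        assert move[0, 0]

    def test_beyond_5km_previous_year_keeps_year(self):
        move = af.relocate_year(self.one_burned_pixel(),
                                self.rec_at(6000, year=2014),
                                self.rec_at(20000), GRID)
        assert not move[0, 0]

    def test_closer_current_year_keeps_year(self):
        move = af.relocate_year(self.one_burned_pixel(),
                                self.rec_at(3000, year=2014),
                                self.rec_at(2000), GRID)
        assert not move[0, 0]

    def test_5km_boundary_inclusive_and_strict_comparison(self):
        # exactly 5 km away and nearer than current year: relocates
        move = af.relocate_year(self.one_burned_pixel(),
                                self.rec_at(5000, year=2014),
                                self.rec_at(6000), GRID)
        assert move[0, 0]
        # equal distances: condition 2 strict, keeps year
        move = af.relocate_year(self.one_burned_pixel(),
                                self.rec_at(3000, year=2014),
                                self.rec_at(3000), GRID)
        assert not move[0, 0]

    def test_no_previous_records_never_relocates(self):
        move = af.relocate_year(self.one_burned_pixel(), records([]),
                                self.rec_at(100), GRID)
        assert not move.any()
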