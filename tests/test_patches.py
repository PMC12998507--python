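"""Flood-fill fire-patch clustering, tile merging and overwintering flags."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from peatfire import patches as pm
from peatfire.patches import ClusterConfig, FirePatch


def day_raster(shape, entries):
    out = np.full(shape, np.nan)
    for (i, j), d in entries.items():
        out[i, j] = d
    return out


def brute_force_patches(day, cutoff, link_m, pixel_size=30.0):
    """O(n^2) transitive closure over all burned-pixel pairs."""
    rr, cc = np.nonzero(np.isfinite(day))
    n = rr.size
    if n == 0:
        return []
    days = day[rr, cc]
    xy = np.column_stack([cc, rr]) * pixel_size
    d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
    adj = (d2 <= link_m**2) & (
        np.abs(days[:, None] - days[None, :]) <= cutoff)
    np.fill_diagonal(adj, False)
    ii, jj = np.nonzero(adj)
    g = coo_matrix((np.ones(ii.size), (ii, jj)), shape=(n, n))
    _, labels = connected_components(g, directed=False)
    comps = {}
    for k, lab in enumerate(labels):
        comps.setdefault(lab, set()).add((int(rr[k]), int(cc[k])))
    return sorted(frozenset(c) for c in comps.values())


def patch_sets(patches):
    return sorted(frozenset(zip(p.rows.tolist(), p.cols.tolist()))
                  for p in patches)


class TestClusterPatches:
    def test_temporal_cutoff_splits_collinear_pixels(self):
        day = day_raster((3, 5), {(1, 1): 100, (1, 2): 110, (1, 3): 140})
        patches = pm.cluster_patches(day)
        days = sorted(tuple(sorted(p.days)) for p in patches)
        assert days == [(100.0, 110.0), (140.0,)]

    def test_150m_buffer_bridges_4_pixel_gap(self):
        # two clusters separated by a 4-pixel river gap (120 m of empty
        # cells; 150 m center-to-center), compatible days -> one patch
        entries = {(1, j): 100 for j in range(3)}
        entries.update({(1, j): 105 for j in range(7, 10)})
        day = day_raster((3, 12), entries)
        assert len(pm.cluster_patches(day)) == 1

    def test_300m_gap_stays_split(self):
        entries = {(1, j): 100 for j in range(3)}
        entries.update({(1, j): 105 for j in range(12, 15)})
        day = day_raster((3, 16), entries)
        assert len(pm.cluster_patches(day)) == 2

    def test_undated_burned_pixel_raises_with_listing(self):
        day = np.full((4, 4), np.nan)
        burned = np.zeros((4, 4), dtype=bool)
        burned[2, 2] = True
        with pytest.raises(pm.UndatedPixelError, match=r"\(2,2\)"):
            pm.cluster_patches(day, burned=burned)

    @pytest.mark.parametrize("cutoff", [12.0, 16.0, 24.0])
    def test_matches_brute_force_oracle(self, rng, cutoff):
        cfg = ClusterConfig(cutoff_days=cutoff)
        for _ in range(10):
            day = np.where(rng.uniform(size=(24, 24)) < 0.25,
                           rng.integers(100, 200, (24, 24)).astype(float),
                           np.nan)
            got = patch_sets(pm.cluster_patches(day, cfg))
            expect = brute_force_patches(day, cutoff, pm._link_radius(cfg, 30.0))
            assert got == expect

    def test_increasing_cutoff_never_increases_patch_count(self, rng):
        day = np.where(rng.uniform(size=(32, 32)) < 0.3,
                       rng.integers(100, 220, (32, 32)).astype(float), np.nan)
        counts = [len(pm.cluster_patches(day, ClusterConfig(cutoff_days=c)))
                  for c in (12, 16, 20, 24)]
        assert counts == sorted(counts, reverse=True)

    def test_patch_attributes(self):
        day = day_raster((4, 4), {(0, 0): 120, (0, 1): 130})
        (p,) = pm.cluster_patches(day, year=2015)
        assert p.start_day == 120 and p.end_day == 130 and p.duration == 10
        assert p.size_ha == pytest.approx(2 * 0.09)


class TestMergeTiles:
    def test_patch_straddling_tiles_is_single(self, rng):
        day = np.full((40, 40), np.nan)
        day[14:18, 10:30] = 150  # crosses the 16-px tile boundary
        cfg = ClusterConfig(tile_size=16)
        merged = pm.merge_tiles(day, cfg)
        assert len(merged) == 1
        assert merged[0].n_pixels == 4 * 20

    def test_equivalent_to_whole_raster_clustering(self, rng):
        # multi-tile scars, each smaller than one tile span (the stated
        # equivalence domain), scattered across a 48x48 / 16-px-tile raster
        cfg = ClusterConfig(tile_size=16)
        for _ in range(5):
            day = np.full((48, 48), np.nan)
            for _ in range(6):
                h, w = rng.integers(2, 9, 2)
                i = int(rng.integers(0, 48 - h))
                j = int(rng.integers(0, 48 - w))
                day[i:i + h, j:j + w] = float(rng.integers(100, 200))
            assert patch_sets(pm.merge_tiles(day, cfg)) == \
                patch_sets(pm.cluster_patches(day, cfg))

    def test_patch_inside_one_tile_unchanged(self):
        day = np.full((40, 40), np.nan)
        day[2:5, 2:5] = 120
        cfg = ClusterConfig(tile_size=20)
        merged = pm.merge_tiles(day, cfg)
        assert patch_sets(merged) == patch_sets(pm.cluster_patches(day, cfg))


def patch_at(rows, cols, days, year=2015, pid=0):
    return FirePatch(patch_id=pid, year=year, rows=np.asarray(rows),
                     cols=np.asarray(cols), days=np.asarray(days, float))


class TestOverwintering:
    def prev(self):
        return [patch_at([10] * 3, [10, 11, 12], [250, 251, 252], 2014, 0)]

    def test_june_start_within_800m_flagged(self):
        # ~26 pixels away = 780 m, start June 15 (day 166)
        p = patch_at([10], [38], [166])
        pm.flag_overwintering([p], self.prev())
        assert p.overwintering and p.origin_patch_id == 0

    def test_july_start_not_flagged(self):
        p = patch_at([10], [13], [191])  # July 10
        pm.flag_overwintering([p], self.prev())
        assert not p.overwintering

    def test_beyond_1km_not_flagged(self):
        p = patch_at([10], [63], [152])  # 51 px = 1530 m
        pm.flag_overwintering([p], self.prev())
        assert not p.overwintering

    def test_no_previous_season_never_flags(self):
        p = patch_at([10], [11], [150])
        pm.flag_overwintering([p], [])
        assert not p.overwintering

    def test_peat_corridor_recorded(self):
        peat = np.zeros((30, 60), dtype=bool)
        peat[10, 20] = True  # between the two patches
        p = patch_at([10], [30], [166])
        pm.flag_overwintering([p], self.prev(), peat_mask=peat)
        assert p.overwintering and p.origin_peat_in_corridor

    def test_leap_year_boundary_shifts(self):
        p = patch_at([10], [13], [182])  # July 1 non-leap: excluded
        pm.flag_overwintering([p], self.prev())
        assert not p.overwintering
        pm.flag_overwintering([p], self.prev(), july1=183)  # leap year
        assert p.overwintering


class TestSummaries:
    def test_small_patch_size(self):
        p = patch_at(np.zeros(100, int), np.arange(100), np.full(100, 150.0))
        tab = pm.patch_summaries([p])
        assert tab.loc[0, "size_ha"] == pytest.approx(9.0)
        assert not tab.loc[0, "large_fire"]

    def test_large_fire_threshold(self):
        n = 11_112
        p = patch_at(np.repeat(np.arange(112), 100)[:n],
                     np.tile(np.arange(100), 112)[:n], np.full(n, 150.0))
        tab = pm.patch_summaries([p])
        assert tab.loc[0, "size_ha"] == pytest.approx(1000.08)
        assert bool(tab.loc[0, "large_fire"])

    def test_empty_patch_set(self):
        tab = pm.patch_summaries([])
        assert tab.empty
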