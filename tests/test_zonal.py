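"""Tests for BCU clipping and zonal reduction of impact rasters."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, box

from reefpressure.grid import Grid
from reefpressure.impact_model import CATEGORIES, compute_impact
from reefpressure.pipeline import load_membership_fixture
from reefpressure.zonal import (
    Zone,
    clip_bcus,
    membership_counts,
    summarize_bcus,
    summarize_countries,
    zonal_mean,
    zone_cell_mask,
)

from conftest import random_impact_inputs


def brute_force_zonal_mean(raster, grid, geometry):
    """Independent oracle: loop every cell, point-in-polygon on its centre."""
    vals = []
    cs = grid.cell_size
    for r in range(grid.rows):
        for c in range(grid.cols):
            x = grid.x0 + (c + 0.5) * cs
            y = grid.y_top - (r + 0.5) * cs
            if geometry.contains(Point(x, y)) and np.isfinite(raster[r, c]):
                vals.append(raster[r, c])
    return float(np.mean(vals)) if vals else float("nan")


class TestZonalMean:
    def test_constant_raster(self):
        grid = Grid((6, 6))
        zone = Zone("z", "bcu", box(1, 1, 5, 5), bcuid=1)
        assert zonal_mean(np.full((6, 6), 3.7), grid, zone) == pytest.approx(3.7)

    def test_four_cell_rectangle(self):
        # 4x4 ramp; zone covers the centers of the bottom-left 2x2 block
        grid = Grid((4, 4))
        raster = np.arange(16.0).reshape(4, 4)
        zone = Zone("z", "bcu", box(0, 0, 2, 2), bcuid=1)
        # bottom two rows are raster rows 2 and 3; cols 0 and 1
        expected = np.mean([raster[2, 0], raster[2, 1], raster[3, 0], raster[3, 1]])
        assert zonal_mean(raster, grid, zone) == pytest.approx(expected)

    def test_zone_outside_extent_warns_nan(self, caplog):
        grid = Grid((4, 4))
        zone = Zone("far", "bcu", box(100, 100, 110, 110), bcuid=1)
        with caplog.at_level("WARNING"):
            out = zonal_mean(np.ones((4, 4)), grid, zone)
        assert np.isnan(out)
        assert "no usable cells" in caplog.text

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_zones(self, seed):
        rng = np.random.default_rng(seed)
        grid = Grid((8, 8))
        raster = rng.normal(size=(8, 8))
        x0, y0 = rng.uniform(0, 6, 2)
        w, h = rng.uniform(1, 4, 2)
        zone = Zone("z", "bcu", box(x0, y0, x0 + w, y0 + h), bcuid=1)
        got = zonal_mean(raster, grid, zone)
        want = brute_force_zonal_mean(raster, grid, zone.geometry)
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, rel=1e-12)

    def test_bounded_by_raster_range(self):
        rng = np.random.default_rng(1)
        grid = Grid((10, 10))
        raster = rng.uniform(2, 9, (10, 10))
        zone = Zone("z", "bcu", box(2, 2, 8, 8), bcuid=1)
        m = zonal_mean(raster, grid, zone)
        assert raster.min() <= m <= raster.max()


class TestClipBcus:
    def _eezs(self):
        return [
            Zone("eez-A", "eez", box(0, 0, 5, 8), country="A"),
            Zone("eez-B", "eez", box(5, 0, 10, 8), country="B"),
        ]

    def test_bcu_inside_one_eez(self):
        bcu = Zone("bcu-1", "bcu", box(1, 1, 4, 4), bcuid=1)
        portions = clip_bcus([bcu], self._eezs())
        assert len(portions) == 1
        assert portions[0].country == "A"
        assert portions[0].geometry.area == pytest.approx(bcu.geometry.area)

    def test_straddling_bcu_partitions_area(self):
        bcu = Zone("bcu-1", "bcu", box(3, 1, 8, 4), bcuid=1)
        portions = clip_bcus([bcu], self._eezs())
        assert len(portions) == 2
        assert sum(p.geometry.area for p in portions) == pytest.approx(
            bcu.geometry.area
        )

    def test_land_overlap_is_trimmed(self):
        # above y=8 is outside every EEZ: the 200-nm clipping drops it
        bcu = Zone("bcu-1", "bcu", box(1, 6, 4, 10), bcuid=1)
        portions = clip_bcus([bcu], self._eezs())
        assert len(portions) == 1
        assert portions[0].geometry.area == pytest.approx(3 * 2)

    def test_portion_count_matches_membership_table(self, small_world):
        geo = small_world.geometry
        portions = clip_bcus(geo.bcu_zones, geo.eez_zones)
        assert len(portions) == len(geo.membership)
        got = {(p.country, p.bcuid) for p in portions}
        want = {(r.country, r.bcuid) for r in geo.membership.itertuples()}
        assert got == want


class TestSummaries:
    def _world_stack(self, small_world):
        layers = [s for s in small_world.stressors if s.period == 2013]
        return compute_impact(layers, small_world.habitats, small_world.vulnerability)

    def test_bcu_mean_pools_cells_across_portions(self, small_world):
        geo = small_world.geometry
        stack = self._world_stack(small_world)
        portions = clip_bcus(geo.bcu_zones, geo.eez_zones)
        summaries = summarize_bcus(portions, stack, geo.grid)
        for s in summaries:
            # oracle: pooled mask over the BCU's portions
            mask = np.zeros(geo.grid.shape, bool)
            for p in portions:
                if p.bcuid == s.bcuid:
                    mask |= zone_cell_mask(geo.grid, p.geometry)
            vals = stack.total[mask]
            vals = vals[np.isfinite(vals)]
            assert s.mean_chi == pytest.approx(vals.mean(), rel=1e-12)
            assert sum(s.pct_contribution.values()) == pytest.approx(1.0, abs=1e-9)
            assert sum(s.mean_per_category.values()) == pytest.approx(
                s.mean_chi, abs=1e-9
            )

    def test_all_climate_world_contribution(self):
        stressors, habitats, vuln = random_impact_inputs(0, n_stressors=3)
        for s in stressors:
            s.category = "climate"
        stack = compute_impact(stressors, habitats, vuln)
        grid = Grid((5, 5))
        portions = [
            Zone("bcu1-A", "bcu_country_portion", box(0, 0, 5, 5), bcuid=1, country="A")
        ]
        (summary,) = summarize_bcus(portions, stack, grid)
        assert summary.pct_contribution["climate"] == pytest.approx(1.0)

    def test_country_mean_of_portion_means(self):
        grid = Grid((4, 8))
        raster = np.zeros((4, 8))
        raster[:, :4] = 2.0
        raster[:, 4:] = 4.0
        from reefpressure.impact_model import ImpactStack

        stack = ImpactStack(
            total=raster,
            per_category={c: raster / 3 for c in CATEGORIES},
            per_stressor={},
        )
        portions = [
            Zone("bcu1-A", "bcu_country_portion", box(0, 0, 4, 4), bcuid=1, country="A"),
            Zone("bcu2-A", "bcu_country_portion", box(4, 0, 8, 4), bcuid=2, country="A"),
        ]
        (summary,) = summarize_countries(portions, stack, grid)
        assert summary.mean_chi == pytest.approx(3.0)
        (pooled,) = summarize_countries(portions, stack, grid, mode="pooled")
        assert pooled.mean_chi == pytest.approx(3.0)  # equal cell counts here

    def test_country_aggregation_permutation_invariant(self, small_world):
        geo = small_world.geometry
        stack = self._world_stack(small_world)
        portions = clip_bcus(geo.bcu_zones, geo.eez_zones)
        fwd = summarize_countries(portions, stack, geo.grid)
        rev = summarize_countries(portions[::-1], stack, geo.grid)
        assert [s.country for s in fwd] == [s.country for s in rev]
        for a, b in zip(fwd, rev):
            assert a.mean_chi == pytest.approx(b.mean_chi, rel=1e-12)

    def test_partition_property(self, small_world):
        geo = small_world.geometry
        portions = clip_bcus(geo.bcu_zones, geo.eez_zones)
        from shapely.ops import unary_union

        eez_union = unary_union([z.geometry for z in geo.eez_zones])
        for bcu in geo.bcu_zones:
            clipped = bcu.geometry.intersection(eez_union)
            total = sum(p.geometry.area for p in portions if p.bcuid == bcu.bcuid)
            assert total == pytest.approx(clipped.area, rel=1e-6)


class TestMembershipCounts:
    def test_packaged_fixture_counts(self):
        table = load_membership_fixture()
        counts = membership_counts(table, country_col="iso3")
        assert counts.n_countries == 28
        assert counts.n_bcus == 50
        assert counts.countries_per_bcu_hist[2] == 8
        assert counts.countries_per_bcu_hist[3] == 4

    def test_single_row_table(self):
        counts = membership_counts(pd.DataFrame({"country": ["A"], "bcuid": [1]}))
        assert counts == (1, 1, {"A": 1}, {1: 1})

    def test_duplicate_rows_error(self):
        table = pd.DataFrame({"country": ["A", "A"], "bcuid": [1, 1]})
        with pytest.raises(ValueError, match="duplicate"):
            membership_counts(table)
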