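"""Tests for the seeded synthetic study-system generator."""

import numpy as np
import pytest

from reefpressure.impact_model import CATEGORIES
from reefpressure.synthetic_world import (
    CHANGE_INELIGIBLE,
    GenerationError,
    WorldConfig,
    generate_geometry,
    generate_metrics,
    generate_stressors,
    generate_world,
    write_world,
)
from reefpressure.zonal import membership_counts


class TestGeometry:
    def test_constraint_satisfaction(self):
        cfg = WorldConfig(grid_shape=(48, 48), n_countries=3, n_bcus=4, seed=7)
        geo = generate_geometry(cfg)
        assert len(geo.bcu_zones) == 4
        spans = geo.membership.groupby("bcuid")["country"].nunique()
        assert ((spans >= 1) & (spans <= 3)).all()
        for z in geo.bcu_zones + geo.eez_zones + geo.land_zones:
            assert z.geometry.is_valid

    def test_eezs_tile_marine_without_overlap(self, small_world):
        geo = small_world.geometry
        eezs = [z.geometry for z in geo.eez_zones]
        for i in range(len(eezs)):
            for j in range(i + 1, len(eezs)):
                assert eezs[i].intersection(eezs[j]).area == pytest.approx(0)
        marine_area = sum(e.area for e in eezs)
        xmin, ymin, xmax, _ = geo.grid.extent
        assert marine_area == pytest.approx((xmax - xmin) * (geo.coast_y - ymin))

    def test_each_bcu_intersects_listed_countries(self, small_world):
        geo = small_world.geometry
        eez_by_country = {z.country: z.geometry for z in geo.eez_zones}
        for bcu in geo.bcu_zones:
            members = set(
                geo.membership.loc[geo.membership.bcuid == bcu.bcuid, "country"]
            )
            hit = {
                c for c, g in eez_by_country.items()
                if bcu.geometry.intersection(g).area > 0
            }
            assert hit == members
            assert 1 <= len(members) <= 3

    def test_single_bcu_inside_one_eez(self):
        cfg = WorldConfig(grid_shape=(32, 32), n_countries=2, n_bcus=1, seed=3)
        geo = generate_geometry(cfg)
        assert len(geo.membership) == geo.membership["bcuid"].nunique() * \
            geo.membership.groupby("bcuid")["country"].nunique().iloc[0]
        counts = membership_counts(geo.membership)
        assert counts.n_bcus == 1

    def test_too_many_bcus_raises(self):
        cfg = WorldConfig(grid_shape=(16, 16), n_countries=2, n_bcus=10, seed=0)
        with pytest.raises(GenerationError, match="1-3 countr"):
            generate_geometry(cfg)

    def test_serialization_is_byte_identical(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_world(generate_world(small_config), d1)
        write_world(generate_world(small_config), d2)
        for p1 in sorted(d1.rglob("*")):
            if p1.is_file():
                p2 = d2 / p1.relative_to(d1)
                assert p1.read_bytes() == p2.read_bytes(), p1.name


class TestStressors:
    def test_trend_direction_recovered_in_marine_means(self):
        cfg = WorldConfig(
            grid_shape=(48, 48), n_countries=4, n_bcus=4, seed=5,
            trend={"climate": 0.3, "land": 0.0, "marine": -0.1},
        )
        geo = generate_geometry(cfg)
        layers = generate_stressors(cfg, geo)
        for cat, cmp in (("climate", np.greater), ("marine", np.less)):
            eligible = [
                s for s in layers if s.category == cat and s.change_eligible
            ]
            m08 = np.nanmean([s.intensity for s in eligible if s.period == 2008])
            m13 = np.nanmean([s.intensity for s in eligible if s.period == 2013])
            assert cmp(m13, m08)

    def test_zero_trend_zero_noise_identical_periods(self):
        cfg = WorldConfig(
            grid_shape=(32, 32), n_countries=3, n_bcus=2, seed=9,
            trend={"climate": 0.0, "land": 0.0, "marine": 0.0},
            temporal_noise_sd=0.0,
        )
        geo = generate_geometry(cfg)
        layers = generate_stressors(cfg, geo)
        by_name = {}
        for s in layers:
            by_name.setdefault(s.name, {})[s.period] = s.intensity
        for name, d in by_name.items():
            np.testing.assert_array_equal(d[2008], d[2013])

    def test_all_values_within_unit_interval(self, small_world):
        for s in small_world.stressors:
            vals = s.intensity[np.isfinite(s.intensity)]
            assert vals.min() >= 0 and vals.max() <= 1

    def test_ineligible_set_mirrors_exclusions(self, small_world):
        flags = {s.name: s.change_eligible for s in small_world.stressors}
        for name in CHANGE_INELIGIBLE:
            assert flags[name] is False
        # ineligible layers are identical across periods ("no comparable data")
        by_name = {}
        for s in small_world.stressors:
            by_name.setdefault(s.name, {})[s.period] = s.intensity
        for name in CHANGE_INELIGIBLE:
            np.testing.assert_array_equal(by_name[name][2008], by_name[name][2013])

    def test_default_stressor_count_is_nineteen(self, small_world):
        names = {s.name for s in small_world.stressors}
        assert len(names) == 19
        per_cat = {
            cat: len({s.name for s in small_world.stressors if s.category == cat})
            for cat in CATEGORIES
        }
        assert per_cat == {"climate": 4, "land": 5, "marine": 10}


class TestMetrics:
    def test_no_missing_when_rate_zero(self):
        cfg = WorldConfig(metric_missing_rate=0.0, seed=2)
        metrics = generate_metrics(cfg)
        assert metrics.table["raw_value"].notna().all()

    def test_noiseless_single_metric_preserves_latent_ranks(self):
        cfg = WorldConfig(
            seed=4, metric_noise_sd=0.0, metric_missing_rate=0.0,
            metrics_per_category={
                "climate": [("m-climate", "higher_better")],
                "marine": [("m-marine", "lower_better")],
                "land": [("m-land", "higher_better")],
            },
        )
        metrics = generate_metrics(cfg)
        for cat in CATEGORIES:
            sub = metrics.table[metrics.table.category == cat].set_index("country")
            raw = sub["raw_value"]
            if sub["direction"].iloc[0] == "lower_better":
                raw = -raw
            latent = metrics.latent[cat]
            assert (
                raw.rank().sort_index() == latent.rank().sort_index()
            ).all()

    def test_seeded_regeneration_identical(self):
        cfg = WorldConfig(seed=8)
        a, b = generate_metrics(cfg), generate_metrics(cfg)
        assert a.table.equals(b.table)
        assert a.latent.equals(b.latent)

    def test_missing_rate_bounds_validated(self):
        with pytest.raises(ValueError, match="metric_missing_rate"):
            WorldConfig(metric_missing_rate=1.0)


class TestTrendRecovery:
    def test_injected_category_trends_recovered_by_change_analysis(self):
        """Sign of the injected climate/marine trends survives the full
        impact + change pipeline across 10 seeds."""
        from reefpressure.impact_model import change_in_impact, compute_impact

        agree = {"climate": 0, "marine": 0}
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = WorldConfig(grid_shape=(32, 32), n_countries=3, n_bcus=3, seed=seed)
            world = generate_world(cfg)
            by_name = {}
            for s in world.stressors:
                by_name.setdefault(s.name, {})[s.period] = s
            stacks = {}
            for period in (2008, 2013):
                stacks[period] = compute_impact(
                    [d[period] for d in by_name.values()],
                    world.habitats,
                    world.vulnerability,
                )
            eligibility = {n: d[2013].change_eligible for n, d in by_name.items()}
            _, delta_cat = change_in_impact(stacks[2008], stacks[2013], eligibility)
            if np.nanmean(delta_cat["climate"]) > 0:
                agree["climate"] += 1
            if np.nanmean(delta_cat["marine"]) < 0:
                agree["marine"] += 1
        assert agree["climate"] == n_seeds
        assert agree["marine"] == n_seeds
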