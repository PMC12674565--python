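from collections import OrderedDict

import numpy as np
import pytest

from srscape.grids import RasterGrid, haversine_km
from srscape.provenance import (EmptyRangeError, assess_sites, assessment_table,
                                deviation_category, deviation_from_range,
                                local_range, pool_site_samples, round2_half_up)
from srscape.samples import SampleRecord, Site, SiteTable


def _const_grid(value=0.710, n=40, cell=0.01):
    return RasterGrid(np.full((n, n), value), 100.0, 48.0, cell, -cell)


def _site(sid, lon, lat, ratios, material="human", period="LBA", source="a"):
    s = Site(sid, lon, lat)
    for k, r in enumerate(ratios):
        s.samples.append(SampleRecord(sid, lon, lat, material, r,
                                      period=period, source=source))
    return s


def _table(*sites):
    return SiteTable(OrderedDict((s.site_id, s) for s in sites))


class TestLocalRange:
    def test_constant_field_any_radius(self):
        g = _const_grid()
        for r in (10, 20, 50):
            assert local_range(g, 100.2, 47.8, r) == (0.710, 0.710)

    def test_matches_exhaustive_scan(self, small_world):
        """Range over a radius spanning several geology units equals a
        brute-force scan over every cell-centre distance."""
        g = small_world.truth
        lon, lat = 99.3, 48.2
        for radius in (7.0, 18.0, 43.0):
            lons, lats = g.cell_centers()
            d = haversine_km(lon, lat, lons, lats)
            mask = (d <= radius) & np.isfinite(g.values)
            expected = (float(g.values[mask].min()), float(g.values[mask].max()))
            assert local_range(g, lon, lat, radius) == expected

    def test_single_cell_radius(self):
        g = RasterGrid(np.arange(16.0).reshape(4, 4) / 100 + 0.70, 100.0, 48.0,
                       0.02, -0.02)
        lons, lats = g.cell_centers()
        v = local_range(g, lons[1, 2], lats[1, 2], 0.5)
        assert v == (g.values[1, 2], g.values[1, 2])

    def test_no_valid_cells_is_explicit_error(self):
        vals = np.full((10, 10), np.nan)
        vals[9, 9] = 0.71
        g = RasterGrid(vals, 100.0, 48.0, 0.01, -0.01)
        with pytest.raises(EmptyRangeError, match="X1"):
            local_range(g, 100.01, 47.99, 1.0, site_id="X1")

    def test_outside_extent_names_site(self):
        with pytest.raises(ValueError, match="far_site"):
            local_range(_const_grid(), 120.0, 47.0, 10, site_id="far_site")


class TestPooling:
    def test_single_sample_mean(self):
        df = pool_site_samples(_table(_site("a", 100.1, 47.9, [0.7101])))
        assert df.loc[0, "mean_ratio"] == 0.7101 and df.loc[0, "n"] == 1

    def test_two_sample_arithmetic(self):
        df = pool_site_samples(_table(_site("a", 100.1, 47.9, [0.710, 0.712])))
        assert df.loc[0, "mean_ratio"] == pytest.approx(0.711)

    def test_multi_study_pooling_matches_groupby_oracle(self):
        site = _site("a", 100.1, 47.9, [0.710, 0.711], source="study1")
        for r in (0.712, 0.713, 0.714):
            site.samples.append(SampleRecord("a", 100.1, 47.9, "human", r,
                                             period="LBA", source="study2"))
        df = pool_site_samples(_table(site))
        assert df.loc[0, "n"] == 5
        assert df.loc[0, "mean_ratio"] == pytest.approx(
            np.mean([0.710, 0.711, 0.712, 0.713, 0.714]))

    def test_archaeological_and_modern_pooled_separately(self):
        site = _site("a", 100.1, 47.9, [0.710], period="LBA")
        site.samples.append(SampleRecord("a", 100.1, 47.9, "human", 0.715,
                                         period="modern"))
        df = pool_site_samples(_table(site))
        assert set(df["epoch_class"]) == {"archaeological", "modern"}
        assert len(df) == 2


class TestAssessment:
    def test_thirteen_of_fourteen_is_92_86_percent(self):
        """14 samples, 13 inside the 10 km range -> 92.86% (two-decimal,
        half-up)."""
        g = _const_grid(0.710)
        ratios = [0.710] * 13 + [0.715]
        [a] = assess_sites(g, _table(_site("bb", 100.2, 47.8, ratios, period="Han")))
        assert a.proportions[10.0] == 92.86
        assert a.proportions[50.0] == 92.86
        assert a.n == 14

    def test_all_inside_constant_field(self):
        g = _const_grid(0.710)
        [a] = assess_sites(g, _table(_site("s", 100.2, 47.8, [0.710] * 4)))
        assert all(a.proportions[r] == 100.00 for r in (10.0, 20.0, 50.0))
        assert a.category == "inside"

    def test_proportions_nondecreasing_when_radius_gains_a_unit(self):
        """Enlarging the radius onto a lower-ratio unit can only add
        samples to the within class; checked against recomputation."""
        vals = np.full((60, 60), 0.715)
        vals[:, :20] = 0.708  # a distant low-ratio unit to the west
        g = RasterGrid(vals, 100.0, 48.0, 0.005, -0.005)
        site = _site("s", 100.22, 47.85, [0.708, 0.715, 0.7152, 0.709])
        [a] = assess_sites(g, _table(site))
        props = [a.proportions[r] for r in (10.0, 20.0, 50.0)]
        assert props == sorted(props)
        a.assert_invariants()
        for r, rng_ in a.ranges.items():
            expected = local_range(g, site.longitude, site.latitude, r)
            assert rng_ == expected
            within = [rng_[0] <= v <= rng_[1] for v in
                      [s.sr_ratio for s in site.samples]]
            assert a.proportions[r] == round2_half_up(100 * np.mean(within))

    def test_boundary_sample_counts_as_local(self):
        vals = np.full((40, 40), 0.710)
        vals[0, 0] = 0.712
        g = RasterGrid(vals, 100.0, 48.0, 0.01, -0.01)
        [a] = assess_sites(g, _table(_site("s", 100.2, 47.8, [0.712])),
                           radii=(50,))
        assert a.proportions[50.0] == 100.00

    def test_summary_only_sites_flagged(self):
        g = _const_grid()
        site = _site("s", 100.2, 47.8, [0.710])
        site.summary_only = True
        [a] = assess_sites(g, _table(site))
        assert all(v is None for v in a.proportions.values())
        assert a.mean_within[10.0]  # mean-based assessment still produced

    def test_table_layout(self):
        g = _const_grid()
        table = _table(_site("s1", 100.2, 47.8, [0.710]),
                       _site("s2", 100.3, 47.7, [0.7099], material="animal"))
        df = assessment_table(assess_sites(g, table))
        assert list(df["site"]) == ["s1", "s2"]
        assert {"pct_within_10km", "pct_within_20km", "pct_within_50km"} <= set(df)


class TestDeviation:
    @pytest.mark.parametrize("value,rng_,dev,cat", [
        (0.7100, (0.7095, 0.7105), 0.0, "inside"),
        (0.71091, (0.7095, 0.7105), 0.00041, "small"),
        (0.7113, (0.7095, 0.7105), 0.0008, "moderate"),
        (0.7120, (0.7095, 0.7105), 0.0015, "large"),
    ])
    def test_categories(self, value, rng_, dev, cat):
        d = deviation_from_range(value, rng_)
        assert d == pytest.approx(dev)
        assert deviation_category(d) == cat


def test_round_half_up_two_decimals():
    assert round2_half_up(92.855) == 92.86
    assert round2_half_up(100 * 13 / 14) == 92.86
    assert round2_half_up(25.004) == 25.0
    assert round2_half_up(0.125) == 0.13
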