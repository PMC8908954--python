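"""Space use: path length, outlier trimming, MCP/KDE home ranges, proximity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Polygon

from settrack import geo
from settrack.reckon import Track
from settrack.simulate import LandscapeFeature, LandscapeLayer, SimConfig, generate_landscape
from settrack.spaceuse import (
    kde_home_range,
    mcp_area,
    path_length,
    proximity_times,
    trim_outliers,
)
from tests.test_geo import haversine


def track_from_projected(e, n, t=None, source="dead_reckoned", dt=0.025):
    e = np.asarray(e, float)
    if t is None:
        t = np.arange(len(e)) * dt
    return Track(t=t, easting=e, northing=np.asarray(n, float), source=source)


class TestPathLength:
    def test_single_fix_zero(self):
        tr = track_from_projected([500000.0], [6020000.0], source="gps")
        assert path_length(tr) == 0.0

    def test_out_and_back_symmetry(self):
        tr = track_from_projected([500000.0, 501000.0, 500000.0],
                                  [6020000.0, 6021000.0, 6020000.0],
                                  source="gps")
        one_way = path_length(track_from_projected(
            [500000.0, 501000.0], [6020000.0, 6021000.0], source="gps"))
        assert path_length(tr) == pytest.approx(2 * one_way, rel=1e-12)

    def test_agrees_with_haversine(self):
        rng = np.random.default_rng(3)
        lat = 54.0 + np.cumsum(rng.uniform(-0.01, 0.01, 50))
        lon = -6.3 + np.cumsum(rng.uniform(-0.01, 0.01, 50))
        e, n = geo.geographic_to_projected(lat, lon)
        tr = track_from_projected(e, n, source="gps")
        ours = path_length(tr)
        ref = float(np.sum(haversine(lat[:-1], lon[:-1], lat[1:], lon[1:]))) / 1000
        assert ours == pytest.approx(ref, rel=0.005)


class TestTrim:
    def test_constructed_outliers_removed(self):
        rng = np.random.default_rng(0)
        inner = rng.uniform(0, 1, (95, 2))
        outer = rng.uniform(9000, 10000, (5, 2))
        pts = np.vstack([inner, outer])
        kept = trim_outliers(pts, 0.05)
        assert len(kept) == 95
        assert kept.max() <= 1.0  # all far points gone

    def test_fraction_zero_identity(self):
        pts = np.random.default_rng(1).normal(0, 1, (40, 2))
        assert np.array_equal(trim_outliers(pts, 0.0), pts)

    def test_identical_points_hull_invariant(self):
        pts = np.tile([3.0, 4.0], (100, 1))
        kept = trim_outliers(pts, 0.05)
        assert len(kept) == 95
        assert np.all(kept == [3.0, 4.0])

    def test_invalid_fraction(self):
        pts = np.zeros((10, 2))
        with pytest.raises(ValueError):
            trim_outliers(pts, 0.5)
        with pytest.raises(ValueError):
            trim_outliers(pts, -0.1)


class TestMcp:
    def test_unit_square_exact(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        hr = mcp_area(pts, level=1.0)
        assert hr.area_km2 == pytest.approx(1e-6, rel=1e-12)
        assert not hr.degenerate

    def test_regular_360gon_closed_form(self):
        n, r = 360, 100.0
        ang = 2 * np.pi * np.arange(n) / n
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        hr = mcp_area(pts, level=1.0)
        closed_form = (n / 2) * r**2 * np.sin(2 * np.pi / n)
        assert hr.area_km2 * 1e6 == pytest.approx(closed_form, rel=1e-9)
        assert hr.area_km2 * 1e6 == pytest.approx(np.pi * r**2, rel=1e-3)

    def test_collinear_degenerate(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        hr = mcp_area(pts, level=1.0)
        assert hr.degenerate
        assert hr.area_km2 == 0.0

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_in_points(self, seed):
        # Adding a point never decreases the untrimmed MCP area.
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 50, (12, 2))
        a_all = mcp_area(pts, level=1.0).area_km2
        a_sub = mcp_area(pts[:-1], level=1.0).area_km2
        assert a_all >= a_sub - 1e-15

    def test_trimming_shrinks_area(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 100, (200, 2))
        assert mcp_area(pts, level=1.0).area_km2 >= \
            mcp_area(pts, level=0.95).area_km2


class TestKde:
    def test_bivariate_normal_analytic_region(self):
        # 95% highest-density region of an isotropic normal has area
        # pi * sigma^2 * chi2_2(0.95).
        rng = np.random.default_rng(11)
        sigma = 100.0
        pts = rng.normal(0, sigma, (10_000, 2))
        hr = kde_home_range(pts, bandwidth=10.0)
        expected = np.pi * sigma**2 * 5.991464547107979 / 1e6
        assert hr.area_km2 == pytest.approx(expected, rel=0.10)
        assert 0.945 <= hr.metadata["contour_mass"] <= 0.955

    def test_two_clusters_disjoint_and_smaller_than_mcp(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 20, (500, 2))
        b = rng.normal(0, 20, (500, 2)) + [1000.0, 0.0]
        pts = np.vstack([a, b])
        hr = kde_home_range(pts, bandwidth=15.0)
        assert hr.n_parts >= 2
        assert hr.area_km2 < mcp_area(pts, level=1.0).area_km2

    def test_grid_resolution_convergence(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 80, (2000, 2))
        a200 = kde_home_range(pts, bandwidth=20.0, grid_res=200).area_km2
        a400 = kde_home_range(pts, bandwidth=20.0, grid_res=400).area_km2
        assert abs(a400 - a200) / a200 < 0.02

    def test_singular_spread_degenerate(self):
        pts = np.tile([5.0, 5.0], (100, 1))
        hr = kde_home_range(pts, bandwidth="reference")
        assert hr.degenerate

    def test_reference_bandwidth_recorded(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 50, (400, 2))
        hr = kde_home_range(pts)
        sd = pts.std(axis=0, ddof=1).mean()
        assert hr.metadata["bandwidth_m"] == pytest.approx(
            sd * 400 ** (-1 / 6), rel=1e-12)


def square_landscape():
    field = Polygon([(0, 0), (280, 0), (280, 200), (0, 200)])
    hedge = Polygon([(300, 0), (305, 0), (305, 200), (300, 200)])
    return LandscapeLayer([LandscapeFeature("field", field),
                           LandscapeFeature("hedge", hedge)])


class TestProximity:
    def test_dr_time_weighting_exact(self):
        # 3600 samples at 40 Hz inside one field -> exactly 90 s.
        land = square_landscape()
        tr = track_from_projected(np.full(3600, 100.0), np.full(3600, 100.0),
                                  t=np.arange(3600) / 40.0)
        budget = proximity_times(tr, land)
        assert budget.times_s["field"] == pytest.approx(90.0, abs=1e-9)
        assert budget.proportions["field"] == pytest.approx(1.0)

    def test_gps_time_weighting_exact(self):
        # 7 hourly fixes near the hedge -> exactly 7 h.
        land = square_landscape()
        tr = track_from_projected(np.full(7, 302.0), np.full(7, 100.0),
                                  t=np.arange(7) * 3600.0, source="gps")
        budget = proximity_times(tr, land)
        assert budget.times_s["hedge"] == pytest.approx(7 * 3600.0, abs=1e-9)

    def test_20m_threshold_semantics(self):
        # 25 m from the hedge, inside the field: counts toward field only.
        land = square_landscape()
        tr = track_from_projected([275.0], [100.0], t=np.array([0.0]),
                                  source="gps")
        budget = proximity_times(tr, land, radius_m=20.0)
        assert budget.times_s["field"] == pytest.approx(3600.0)
        assert budget.times_s["hedge"] == 0.0

    def test_classes_non_exclusive(self):
        land = square_landscape()
        # inside the field and within 20 m of nothing else... move next to
        # hedge: point at x=290 is 10 m from hedge and 90 m outside field?
        # No: field ends at 200; point (190, 100) is inside field only.
        tr = track_from_projected([302.5], [100.0], t=np.array([0.0]),
                                  source="gps")
        budget = proximity_times(tr, land, radius_m=150.0)
        # with a big radius the point is near both classes
        assert budget.times_s["field"] > 0
        assert budget.times_s["hedge"] > 0

    def test_per_class_time_bounded_by_total(self, full_study):
        res = full_study["result"]
        m = res.metrics
        for _, row in m.iterrows():
            for cls in ("field", "hedge", "building", "road"):
                assert 0.0 <= row[f"prop_{cls}"] <= 1.0 + 1e-12

    def test_unknown_source_errors(self):
        land = square_landscape()
        tr = track_from_projected([1.0], [1.0], t=np.array([0.0]),
                                  source="mixed")
        with pytest.raises(ValueError, match="source"):
            proximity_times(tr, land)


def test_exclusive_partition_times_sum(full_study):
    # When classes are made disjoint, per-class times must add up to the
    # time spent in the union.
    import shapely
    from shapely.ops import unary_union

    bundle = full_study["bundle"]
    land = bundle.landscape
    tr = full_study["result"].dr_tracks[(0, 0)]
    radius = 20.0
    buffered = {c: unary_union([g.buffer(radius) for g in land.by_class(c)])
                for c in ("field", "hedge", "building", "road")}
    union_all = unary_union(list(buffered.values()))
    in_union = shapely.contains_xy(union_all, tr.easting, tr.northing).sum()
    # make classes disjoint by subtracting earlier classes
    taken = None
    total = 0
    for c, geom in buffered.items():
        g = geom if taken is None else geom.difference(taken)
        total += shapely.contains_xy(g, tr.easting, tr.northing).sum()
        taken = geom if taken is None else unary_union([taken, geom])
    assert total == in_union
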