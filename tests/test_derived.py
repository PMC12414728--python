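import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bagmove import bagging
from bagmove.derived import (
    FeatureGeometry,
    derived_interval,
    displacement,
    displacement_quantity,
    interval_displacements,
    mean_displacement_quantity,
    min_distance,
    proportion_within,
    proportion_within_quantity,
    read_points_csv,
    read_segments_csv,
)
from bagmove.learners import LearnerSpec
from bagmove.telemetry import PathOnGrid, TimeGrid, make_grid


def _path(times, xs, ys, spacing=None):
    grid = TimeGrid(np.asarray(times, dtype=float), spacing or float(np.max(np.diff(times))))
    return PathOnGrid(grid, np.asarray(xs, dtype=float), np.asarray(ys, dtype=float))


class TestDisplacement:
    def test_same_endpoints_zero(self):
        p = _path([0, 1, 2], [0, 3, 9], [0, 4, 9])
        assert displacement(p, 1, 1) == 0.0

    def test_three_four_five(self):
        p = _path([0, 1], [0, 3], [0, 4])
        assert displacement(p, 0, 1) == 5.0

    def test_invariant_under_rigid_motion(self, rng):
        times = np.arange(10, dtype=float)
        xs, ys = rng.normal(size=10), rng.normal(size=10)
        base = displacement(_path(times, xs, ys), 2, 8)
        theta = 0.7
        xr = math.cos(theta) * xs - math.sin(theta) * ys + 50
        yr = math.sin(theta) * xs + math.cos(theta) * ys - 20
        assert displacement(_path(times, xr, yr), 2, 8) == pytest.approx(base, abs=1e-9)

    def test_triangle_inequality_through_midpoint(self, rng):
        times = np.arange(20, dtype=float)
        p = _path(times, rng.normal(size=20), rng.normal(size=20))
        d_direct = displacement(p, 0, 19)
        assert d_direct <= displacement(p, 0, 10) + displacement(p, 10, 19) + 1e-12

    def test_time_outside_range_rejected(self):
        p = _path([0, 1], [0, 1], [0, 1])
        with pytest.raises(ValueError):
            displacement(p, 0, 5)


class TestIntervalDisplacements:
    def test_constant_speed_line(self):
        t = np.arange(6, dtype=float)
        p = _path(t, 3 * t, 4 * t)  # speed 5 per unit time
        d, mean = interval_displacements(p, t)
        np.testing.assert_allclose(d, 5.0)
        assert mean == 5.0

    def test_two_boundaries_reduce_to_displacement(self, rng):
        t = np.arange(10, dtype=float)
        p = _path(t, rng.normal(size=10), rng.normal(size=10))
        d, mean = interval_displacements(p, [2.0, 7.0])
        assert d.size == 1
        assert mean == pytest.approx(displacement(p, 2, 7))

    def test_stationary_jump_stationary(self):
        t = np.arange(6, dtype=float)
        x = np.array([0, 0, 0, 100, 100, 100], dtype=float)
        p = _path(t, x, np.zeros(6))
        d, mean = interval_displacements(p, t)
        assert d.tolist() == [0, 0, 100, 0, 0]
        assert mean == 20.0

    def test_needs_two_boundaries(self):
        p = _path([0, 1], [0, 1], [0, 1])
        with pytest.raises(ValueError):
            interval_displacements(p, [0.5])


class TestMinDistance:
    def test_perpendicular_foot_inside_segment(self):
        g = FeatureGeometry(segments=[[[-1, 0], [1, 0]]])
        assert min_distance((0, 1), g) == 1.0

    def test_endpoint_clamp(self):
        g = FeatureGeometry(segments=[[[-1, 0], [1, 0]]])
        assert min_distance((2, 0), g) == 1.0

    def test_nearest_of_several_points(self):
        g = FeatureGeometry(points=[(0, 0), (10, 0)])
        assert min_distance((4, 3), g) == 5.0

    def test_degenerate_segment_is_a_point(self):
        g = FeatureGeometry(segments=[[[3, 4], [3, 4]]])
        assert min_distance((0, 0), g) == 5.0

    def test_empty_geometry_rejected(self):
        with pytest.raises(ValueError):
            FeatureGeometry()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=80, deadline=None)
    def test_matches_shapely(self, seed):
        shapely = pytest.importorskip("shapely")
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-10, 10, (3, 2))
        segs = rng.uniform(-10, 10, (3, 2, 2))
        g = FeatureGeometry(points=pts, segments=segs)
        q = tuple(rng.uniform(-12, 12, 2))
        expected = min(
            min(shapely.Point(p).distance(shapely.Point(q)) for p in pts),
            min(shapely.LineString(s).distance(shapely.Point(q)) for s in segs),
        )
        assert min_distance(q, g) == pytest.approx(expected, abs=1e-9)


class TestProportionWithin:
    def test_everything_inside(self):
        t = np.arange(5, dtype=float)
        p = _path(t, np.zeros(5), np.zeros(5))
        g = FeatureGeometry(points=[(0.5, 0.0)])
        assert proportion_within(p, g, 10.0) == 1.0

    def test_radius_zero_off_feature(self):
        t = np.arange(5, dtype=float)
        p = _path(t, np.arange(5.0) + 0.5, np.zeros(5))
        g = FeatureGeometry(points=[(100.0, 0.0)])
        assert proportion_within(p, g, 0.0) == 0.0

    def test_three_of_ten_within(self):
        t = np.arange(10, dtype=float)
        xs = np.array([0, 0, 0, 50, 50, 50, 50, 50, 50, 50], dtype=float)
        p = _path(t, xs, np.zeros(10))
        g = FeatureGeometry(points=[(0.0, 0.0)])
        assert proportion_within(p, g, 1.0) == pytest.approx(0.3)

    def test_monotone_in_radius(self, rng):
        t = np.arange(30, dtype=float)
        p = _path(t, rng.uniform(0, 100, 30), rng.uniform(0, 100, 30))
        g = FeatureGeometry(points=rng.uniform(0, 100, (4, 2)))
        props = [proportion_within(p, g, r) for r in (0, 5, 20, 60, 200)]
        assert props == sorted(props)

    def test_non_uniform_grid_rejected(self):
        p = _path([0, 1, 10], [0, 0, 0], [0, 0, 0])
        g = FeatureGeometry(points=[(0, 0)])
        with pytest.raises(ValueError, match="uniform"):
            proportion_within(p, g, 1.0)


class TestGeometryCsv:
    def test_points_and_segments(self, tmp_path):
        pts = tmp_path / "pts.csv"
        pts.write_text("x,y\n0,0\n5,5\n")
        segs = tmp_path / "segs.csv"
        segs.write_text("x1,y1,x2,y2\n0,0,1,0\n")
        g1 = read_points_csv(pts)
        g2 = read_segments_csv(segs)
        assert g1.points.shape == (2, 2)
        assert g2.segments.shape == (1, 2, 2)


class TestDerivedInterval:
    @pytest.fixture
    def model(self, noisy_telemetry):
        return bagging.fit(
            noisy_telemetry, LearnerSpec("knn", 5), B=40, rng=np.random.default_rng(11)
        )

    def test_identical_members_zero_width(self, constant_telemetry, rng):
        model = bagging.fit(constant_telemetry, LearnerSpec("knn", 3), B=10, rng=rng)
        q = displacement_quantity("d", 10.0, 60.0)
        res = derived_interval(model, q)
        assert res.lower == res.upper == res.estimate == 0.0

    def test_quantile_contract_linear_interpolation(self, model):
        t0, t1 = model.telemetry.time_range
        q = displacement_quantity("d", t0 + 10, t1 - 10)
        res = derived_interval(model, q, level=0.95)
        lo, hi = np.quantile(res.ensemble_values, [0.025, 0.975])
        assert res.lower == pytest.approx(lo) and res.upper == pytest.approx(hi)
        assert res.ensemble_values.size == model.B

    def test_bounds_widen_with_level(self, model):
        t0, t1 = model.telemetry.time_range
        q = displacement_quantity("d", t0 + 10, t1 - 10)
        narrow = derived_interval(model, q, level=0.90)
        wide = derived_interval(model, q, level=0.99)
        assert wide.upper - wide.lower >= narrow.upper - narrow.lower

    def test_component_view_consistent_with_scalar(self, model):
        t0, t1 = model.telemetry.time_range
        bounds = np.linspace(t0 + 5, t1 - 5, 8)
        q = mean_displacement_quantity("dbar", bounds)
        preds = model.member_predictions(q.grid.points)
        scalar = q.evaluate_stack(preds)
        comp = q.component_batch(preds)
        np.testing.assert_allclose(comp.mean(axis=1), scalar, atol=1e-9)

    def test_batch_agrees_with_path_functional(self, model, rng):
        t0, t1 = model.telemetry.time_range
        grid = TimeGrid(np.arange(t0, t1, 10.0), 10.0)
        geometry = FeatureGeometry(points=rng.uniform(-50, 50, (3, 2)))
        q = proportion_within_quantity("p", geometry, 25.0, grid)
        preds = model.member_predictions(grid.points)
        batch_vals = q.evaluate_stack(preds)
        path_vals = [q(p) for p in model.member_paths(grid)]
        np.testing.assert_allclose(batch_vals, path_vals, atol=1e-12)

    def test_interval_needs_two_members(self, constant_telemetry, rng):
        model = bagging.fit(constant_telemetry, LearnerSpec("knn", 3), B=1, rng=rng)
        with pytest.raises(ValueError):
            derived_interval(model, displacement_quantity("d", 10.0, 60.0))
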