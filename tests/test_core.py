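"""Unit and property tests for the extension-approach IDW primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stidw import (AxisScales, IdwConfig, Measurement, build_station_tree,
                   compute_scale_factor, idw_value, interpolate_point,
                   scaled_time, select_neighbors, st_distance)
from stidw.errors import InvalidExtentError, NoDataError, NoNeighborsError
from stidw.kdtree import KdTree

from .conftest import CONUS


class TestScaleFactor:
    @pytest.mark.parametrize("extent, n_days, expected", [
        (CONUS, 365, 0.1086),          # the printed CONUS extent over 2009
        ((0, 364, 0, 364), 365, 1.0),  # mean spatial range equals time span
        ((0, 10, 0, 20), 365, 15 / 364),
    ])
    def test_closed_form(self, extent, n_days, expected):
        x_min, x_max, y_min, y_max = extent
        c = compute_scale_factor(x_min, x_max, y_min, y_max, n_days)
        assert round(c, 4) == round(expected, 4)
        assert c == pytest.approx(((x_max - x_min) + (y_max - y_min)) / 2 / (n_days - 1))

    @pytest.mark.parametrize("extent, n_days", [
        ((0, 0, 0, 1), 10),   # zero x-range
        ((0, 1, 1, 1), 10),   # zero y-range
        ((0, 1, 0, 1), 1),    # single day: no time span
    ])
    def test_degenerate_extent_rejected(self, extent, n_days):
        with pytest.raises(InvalidExtentError):
            compute_scale_factor(*extent, n_days)

    def test_from_extent_sets_unit_spatial_scales(self):
        scales = AxisScales.from_extent(*CONUS, 365)
        assert scales.cx == scales.cy == 1.0
        assert round(scales.ct, 4) == 0.1086


class TestScaledTime:
    @pytest.mark.parametrize("day, c, expected", [
        (365, 0.1086, 39.6390),  # 31 December entry of the study's table
        (4, 0.1086, 0.4344),     # 4 January entry
        (0, 0.37, 0.0),
    ])
    def test_values(self, day, c, expected):
        assert scaled_time(day, c) == pytest.approx(expected)


class TestStDistance:
    def test_identity_is_zero(self):
        scales = AxisScales(ct=0.1)
        assert st_distance((1.0, 2.0, 5), (1.0, 2.0, 5), scales) == 0.0

    def test_planar_345_triangle(self):
        assert st_distance((0, 0, 0), (3, 4, 0), AxisScales(ct=7.7)) == pytest.approx(5.0)

    def test_pure_time_separation(self):
        assert st_distance((0, 0, 0), (0, 0, 10), AxisScales(ct=0.5)) == pytest.approx(5.0)

    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6),
           st.floats(0.01, 10))
    def test_symmetric(self, coords, ct):
        a, b = tuple(coords[:3]), tuple(coords[3:])
        scales = AxisScales(ct=ct)
        assert st_distance(a, b, scales) == pytest.approx(st_distance(b, a, scales))


class TestIdwValue:
    def test_single_neighbor_takes_all_weight(self):
        value, weights = idw_value([(5.0, 2.0)], 2.0)
        assert value == 5.0
        assert [w.weight for w in weights] == [1.0]

    @pytest.mark.parametrize("p, expected_value, expected_weights", [
        (1.0, 1.0, [2 / 3, 1 / 3]),
        (2.0, 0.6, [0.8, 0.2]),
    ])
    def test_hand_worked_two_neighbors(self, p, expected_value, expected_weights):
        value, weights = idw_value([(0.0, 1.0), (3.0, 2.0)], p)
        assert value == pytest.approx(expected_value)
        assert [w.weight for w in weights] == pytest.approx(expected_weights)

    def test_zero_distance_neighbors_average_and_share_weight(self):
        value, weights = idw_value([(4.0, 0.0), (8.0, 0.0), (100.0, 1.0)], 2.0)
        assert value == 6.0
        assert [w.weight for w in weights] == [0.5, 0.5, 0.0]

    def test_empty_list_rejected(self):
        with pytest.raises(NoNeighborsError):
            idw_value([], 2.0)

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0.01, 50)),
                    min_size=1, max_size=12),
           st.floats(0.1, 6))
    def test_weights_normalized_and_value_convex(self, neighbors, p):
        value, weights = idw_value(neighbors, p)
        assert sum(w.weight for w in weights) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= w.weight <= 1.0 for w in weights)
        values = [v for v, _ in neighbors]
        assert min(values) - 1e-9 <= value <= max(values) + 1e-9

    def test_large_exponent_approaches_nearest_neighbor(self, rng):
        checked = 0
        while checked < 25:
            distances = sorted(float(d) for d in rng.uniform(0.1, 5, 6))
            if distances[1] / distances[0] < 1.2:
                continue  # near-tied nearest pair: the limit is not identifiable
            values = [float(v) for v in rng.uniform(0, 30, 6)]
            value, _ = idw_value(list(zip(values, distances)), 50.0)
            assert value == pytest.approx(values[0], rel=1e-3, abs=1e-3)
            checked += 1


def _measurement(day, dt, x=0.0):
    return Measurement(f"s{day}", x, 0.0, day, 1.0), dt


class TestSelectNeighbors:
    # the study's restricted-neighborhood parameters: 1.4 distance, 7 days
    IMPROVED = IdwConfig(3, 2.0, "improved", max_distance=1.4, max_time_diff=7)

    def _candidates(self, query_day=10):
        a = Measurement("A", 0, 0, query_day + 1, 1.0)
        b = Measurement("B", 0, 0, query_day + 20, 2.0)
        c = Measurement("C", 0, 0, query_day, 3.0)
        return [(a, 0.5), (b, 1.2), (c, 2.0)]

    def test_improved_applies_both_filters(self):
        kept = select_neighbors(self._candidates(), 10, self.IMPROVED)
        assert [m.site_id for m, _ in kept] == ["A"]

    def test_original_keeps_everything(self):
        config = IdwConfig(3, 2.0, "original")
        kept = select_neighbors(self._candidates(), 10, config)
        assert [m.site_id for m, _ in kept] == ["A", "B", "C"]

    def test_all_filtered_yields_empty(self):
        config = IdwConfig(3, 2.0, "improved", max_distance=0.1, max_time_diff=0)
        assert select_neighbors(self._candidates(), 50, config) == []


class TestInterpolatePoint:
    def _tree_and_scales(self, measurements):
        scales = AxisScales(ct=0.5)
        return build_station_tree(measurements, scales), scales

    def test_exact_at_measured_point(self):
        ms = [Measurement(i, float(i), float(i % 3), 1 + i % 4, 10.0 + i)
              for i in range(20)]
        tree, scales = self._tree_and_scales(ms)
        config = IdwConfig(4, 2.0)
        for m in ms[:5]:
            rec = interpolate_point(tree, (m.x, m.y, m.day), config, scales,
                                    target_id="t")
            assert rec.value == pytest.approx(m.value)

    def test_exact_mean_over_colocated_duplicates(self):
        ms = [Measurement("a", 1.0, 1.0, 2, 4.0),
              Measurement("b", 1.0, 1.0, 2, 8.0),
              Measurement("c", 9.0, 9.0, 2, 100.0)]
        tree, scales = self._tree_and_scales(ms)
        rec = interpolate_point(tree, (1.0, 1.0, 2), IdwConfig(3, 2.0), scales)
        assert rec.value == pytest.approx(6.0)

    def test_isolated_query_goes_missing_under_improved(self):
        ms = [Measurement(i, 0.0, 0.0, 1, 5.0) for i in range(3)]
        tree, scales = self._tree_and_scales(ms)
        config = IdwConfig(3, 2.0, "improved", max_distance=1.0, max_time_diff=7)
        rec = interpolate_point(tree, (50.0, 50.0, 1), config, scales, "far")
        assert rec.value is None and rec.neighbors_used == 0

    def test_empty_tree_rejected(self):
        empty = KdTree(None, 3, 0)
        with pytest.raises(NoDataError):
            interpolate_point(empty, (0, 0, 1), IdwConfig(3, 2.0), AxisScales())

    def test_scale_consistency_under_common_rescale(self, rng):
        """Multiplying all axis scales by one constant changes no prediction."""
        ms = [Measurement(i, float(x), float(y), int(d), float(v))
              for i, (x, y, d, v) in enumerate(zip(
                  rng.uniform(0, 10, 30), rng.uniform(0, 10, 30),
                  rng.integers(1, 8, 30), rng.uniform(5, 25, 30)))]
        config = IdwConfig(5, 2.5)
        base = AxisScales(1.0, 1.0, 0.7)
        scaled = AxisScales(3.0, 3.0, 2.1)
        tree_a = build_station_tree(ms, base)
        tree_b = build_station_tree(ms, scaled)
        for _ in range(10):
            q = (float(rng.uniform(0, 10)), float(rng.uniform(0, 10)),
                 int(rng.integers(1, 8)))
            ra = interpolate_point(tree_a, q, config, base)
            rb = interpolate_point(tree_b, q, config, scaled)
            assert ra.value == pytest.approx(rb.value, rel=1e-9)


class TestValidation:
    def test_measurement_rejects_bad_day(self):
        with pytest.raises(ValueError):
            Measurement("s", 0.0, 0.0, 0, 1.0)

    def test_measurement_rejects_non_finite(self):
        with pytest.raises(ValueError):
            Measurement("s", math.nan, 0.0, 1, 1.0)

    def test_axis_scales_must_be_positive(self):
        with pytest.raises(ValueError):
            AxisScales(ct=0.0)

    def test_config_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            IdwConfig(0, 2.0)
        with pytest.raises(ValueError):
            IdwConfig(3, 0.0)
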