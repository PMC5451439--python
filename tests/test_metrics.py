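"""Error measures: Jaccard distance, series error, wave speed, boundary
distance, E2, volumes, conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomafit.geometry import Grid3D, ImagingSeries, Params
from gliomafit import metrics
from gliomafit.metrics import (
    ErrorReport,
    boundary_distance_error,
    jaccard_distance,
    percent_decrease,
    point_to_polygon_distances,
    relative_invasiveness,
    total_error_E2,
    umh_to_cmyr,
    visible_volume,
    wave_speed,
)


def _mask(shape, idx):
    m = np.zeros(shape, dtype=bool)
    for i in idx:
        m[i] = True
    return m


class TestJaccard:
    def test_identical_nonempty_sets(self):
        a = _mask((4, 4, 1), [(0, 0, 0), (1, 2, 0)])
        assert jaccard_distance(a, a) == 0.0

    def test_disjoint_nonempty_sets(self):
        a = _mask((4, 4, 1), [(0, 0, 0)])
        b = _mask((4, 4, 1), [(3, 3, 0)])
        assert jaccard_distance(a, b) == 1.0

    def test_partial_overlap(self):
        # |A n B| = 1, |A u B| = 4 -> 0.75
        a = _mask((4, 4, 1), [(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        b = _mask((4, 4, 1), [(0, 0, 0), (3, 3, 0)])
        assert jaccard_distance(a, b) == pytest.approx(0.75)

    def test_empty_set_conventions(self):
        e = np.zeros((3, 3, 1), dtype=bool)
        a = _mask((3, 3, 1), [(1, 1, 0)])
        assert jaccard_distance(e, e) == 0.0
        assert jaccard_distance(a, e) == 1.0
        assert jaccard_distance(e, a) == 1.0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.tuples(
            st.sets(st.integers(0, 11), min_size=1, max_size=12),
            st.sets(st.integers(0, 11), min_size=1, max_size=12),
            st.sets(st.integers(0, 11), min_size=1, max_size=12),
        )
    )
    def test_metric_properties_on_nonempty_sets(self, triple):
        sa, sb, sc = triple
        shape = (12, 1, 1)
        a, b, c = (_mask(shape, [(i, 0, 0) for i in s]) for s in (sa, sb, sc))
        dab = jaccard_distance(a, b)
        assert dab == pytest.approx(jaccard_distance(b, a))
        # triangle inequality of the Jaccard metric
        assert dab <= jaccard_distance(a, c) + jaccard_distance(c, b) + 1e-12


class TestSeriesError:
    def _series(self, masks, geometry):
        days = tuple(range(11, 11 + len(masks)))
        return ImagingSeries(geometry=geometry, days=days, masks=tuple(masks))

    def test_perfect_fit_both_modes(self, small_geometry):
        m = _mask(small_geometry.grid.shape, [(1, 1, 1), (2, 2, 2)])
        series = self._series([m, m, m], small_geometry)
        for mode in ("mean", "sum"):
            rep = metrics.series_error([m, m], series, mode=mode)
            assert rep.aggregate == 0.0
            assert rep.n == 2  # initialisation day excluded

    def test_single_point_mean_equals_sum(self, small_geometry):
        a = _mask(small_geometry.grid.shape, [(1, 1, 1)])
        b = _mask(small_geometry.grid.shape, [(1, 1, 1), (2, 1, 1)])
        series = self._series([a, b], small_geometry)
        mean = metrics.series_error([a], series, "mean")
        total = metrics.series_error([a], series, "sum")
        assert mean.aggregate == total.aggregate == pytest.approx(0.5)

    def test_published_mouse1_sequential_errors(self):
        # per-interval Jaccard distances of the sequential fits
        per_day = (0.1196, 0.1191, 0.1029, 0.0949)
        assert ErrorReport(per_day, "mean").aggregate == pytest.approx(0.109125)
        assert ErrorReport(per_day, "sum").aggregate == pytest.approx(0.4365)

    def test_mean_is_sum_over_n(self):
        per_day = (0.2, 0.4, 0.1)
        assert ErrorReport(per_day, "mean").aggregate * 3 == pytest.approx(
            ErrorReport(per_day, "sum").aggregate
        )


class TestWaveSpeed:
    @pytest.mark.parametrize(
        "D,rho,expected",
        [
            (413.77, 0.0188, 5.5781),
            (319.22, 0.0167, 4.6178),
            (316.43, 0.0226, 5.3484),
        ],
    )
    def test_published_velocity_rows(self, D, rho, expected):
        assert wave_speed(Params(D, rho)) == pytest.approx(expected, abs=5e-5)

    def test_strictly_increasing_in_each_parameter(self):
        base = wave_speed(Params(400.0, 0.02))
        assert wave_speed(Params(500.0, 0.02)) > base
        assert wave_speed(Params(400.0, 0.03)) > base

    @pytest.mark.parametrize(
        "umh,cmyr",
        [(3.1838, 2.789), (9.1280, 7.996), (6.5487, 5.737), (11.1431, 9.761), (0.0, 0.0)],
    )
    def test_speed_conversion_to_cm_per_year(self, umh, cmyr):
        assert umh_to_cmyr(umh) == pytest.approx(cmyr, abs=5e-4)


class TestVolumesAndScalars:
    def test_visible_volume(self):
        grid = Grid3D((10, 10, 10))
        assert visible_volume(np.zeros(grid.shape, bool), grid) == 0.0
        m = np.zeros(grid.shape, bool)
        m.flat[:200] = True
        assert visible_volume(m, grid) == pytest.approx(1.0)  # 200 x 0.005 mm^3
        m2 = np.zeros((30, 30, 30), bool)
        m2.flat[:2468] = True
        assert visible_volume(m2, Grid3D((30, 30, 30))) == pytest.approx(12.34)

    def test_relative_invasiveness(self):
        assert relative_invasiveness(Params(0.5, 0.5)) == 0.0
        assert relative_invasiveness(Params(463.09, 0.027164)) == pytest.approx(4.2317, abs=5e-5)
        a = relative_invasiveness(Params(413.77, 0.0188))
        b = relative_invasiveness(Params(4137.7, 0.188))
        assert a == pytest.approx(b, abs=1e-12)

    def test_percent_decrease(self):
        assert percent_decrease(0.4524, 0.4365) == pytest.approx(3.5, abs=0.05)
        assert percent_decrease(0.4524, 0.3673) == pytest.approx(18.8, abs=0.05)
        assert percent_decrease(0.3, 0.3) == 0.0
        with pytest.raises(ValueError):
            percent_decrease(0.0, 0.1)


def _brute_point_segment(p, a, b):
    ab = b - a
    t = np.dot(p - a, ab) / np.dot(ab, ab)
    t = min(max(t, 0.0), 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


class TestBoundaryDistance:
    square = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])

    def test_identical_polygons(self):
        assert boundary_distance_error([self.square] * 4, [self.square] * 4) == 0.0

    def test_translated_square_matches_bruteforce(self):
        shifted = self.square + np.array([0.3, 0.0])
        # brute-force oracle over all vertex/segment pairs
        expected_rms = np.sqrt(
            np.mean(
                [
                    min(
                        _brute_point_segment(p, self.square[i], self.square[(i + 1) % 4])
                        for i in range(4)
                    )
                    ** 2
                    for p in shifted
                ]
            )
        )
        got = boundary_distance_error([shifted], [self.square])
        assert got == pytest.approx(expected_rms, abs=1e-12)
        d = point_to_polygon_distances(shifted, self.square)
        assert d == pytest.approx([0.0, 0.3, 0.3, 0.0], abs=1e-12)

    def test_vertices_on_data_polygon_give_zero(self):
        # simulated vertices all on the boundary, different vertex count
        dense = np.array(
            [[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1], [0.5, 1], [0, 1], [0, 0.5]],
            dtype=float,
        )
        assert boundary_distance_error([dense], [self.square]) == 0.0

    def test_rejects_degenerate_boundaries(self):
        with pytest.raises(ValueError):
            boundary_distance_error([np.zeros((2, 2))], [self.square])


class TestTotalErrorE2:
    def test_values(self):
        assert total_error_E2(0.0, [0, 0, 0, 0]) == 0.0
        assert total_error_E2(1.5, (0.1, 0.2, 0.3, 0.4)) == pytest.approx(11.5)

    def test_linearity_in_jaccard_term(self):
        j = (0.05, 0.1, 0.2, 0.15)
        base = total_error_E2(0.0, j)
        assert total_error_E2(0.0, tuple(2 * x for x in j)) == pytest.approx(2 * base)
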