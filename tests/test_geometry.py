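"""Morphometric operations against brute-force and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from epistrat.geometry import (
    CellShape,
    FieldOfView,
    InvalidShapeError,
    axial_difference,
    cell_height,
    density,
    elongation_nematic,
    height_width_ratio,
    hertwig_alignment,
    longest_planar_axis,
    neighbor_counts_from_polygons,
    polygon_area,
    polygon_class_distribution,
    proliferation_rate,
    tissue_thickness,
)


def random_star_polygon(rng, n=8, scale=10.0):
    """Simple polygon, star-shaped about the origin (angular gaps < 180°)."""
    ang = 2 * np.pi * (np.arange(n) + rng.uniform(0, 0.95, n)) / n
    r = rng.uniform(0.5, 1.0, n) * scale
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def fan_triangulation_area(v):
    """Independent area oracle: unsigned fan triangles from the star centre.

    The random polygons are star-shaped about the origin (every angular
    gap < 180°), so the fan triangles (0, v_i, v_{i+1}) partition the
    polygon without overlap.
    """
    total = 0.0
    for i in range(len(v)):
        b, c = v[i], v[(i + 1) % len(v)]
        total += 0.5 * abs(b[0] * c[1] - c[0] * b[1])
    return total


def brute_force_longest_chord(v):
    best, pair = -1.0, None
    for i in range(len(v)):
        for j in range(i + 1, len(v)):
            d = np.hypot(*(v[j] - v[i]))
            if d > best:
                best, pair = d, (i, j)
    dx, dy = v[pair[1]] - v[pair[0]]
    return best, np.degrees(np.arctan2(dy, dx)) % 180.0


class TestArea:
    def test_unit_square(self):
        sq = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert polygon_area(sq) == pytest.approx(1.0)
        assert polygon_area(sq[::-1]) == pytest.approx(1.0)  # orientation invariance

    def test_right_triangle(self):
        assert polygon_area([(0, 0), (4, 0), (0, 3)]) == pytest.approx(6.0)

    def test_self_intersecting_rejected(self):
        with pytest.raises(InvalidShapeError):
            polygon_area([(0, 0), (1, 1), (1, 0), (0, 1)])  # bowtie

    def test_against_triangulation_oracle(self, rng):
        for _ in range(50):
            v = random_star_polygon(rng, n=int(rng.integers(4, 12)))
            assert polygon_area(v) == pytest.approx(
                fan_triangulation_area(v), rel=1e-9
            )


class TestHeight:
    def test_basic(self):
        assert cell_height(7.89, 0.0) == pytest.approx(7.89)

    def test_degenerate_zero(self):
        assert cell_height(3.0, 3.0) == 0.0

    def test_negative_extent_rejected(self):
        with pytest.raises(ValueError):
            cell_height(1.0, 2.0)


class TestLongestAxis:
    def test_rectangle_diagonal(self):
        rect = [(0, 0), (4, 0), (4, 2), (0, 2)]
        length, orient = longest_planar_axis(rect)
        assert length == pytest.approx(np.sqrt(20.0))
        assert orient == pytest.approx(np.degrees(np.arctan2(2, 4)))

    def test_regular_hexagon(self):
        ang = np.arange(6) * 60.0
        hexagon = np.column_stack([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
        length, _ = longest_planar_axis(hexagon)
        assert length == pytest.approx(2.0)

    def test_orientation_is_axial(self, rng):
        v = random_star_polygon(rng)
        _, orient = longest_planar_axis(v)
        assert 0.0 <= orient < 180.0

    def test_against_brute_force(self, rng):
        for _ in range(50):
            v = random_star_polygon(rng, n=int(rng.integers(4, 14)))
            length, orient = longest_planar_axis(v)
            exp_len, exp_orient = brute_force_longest_chord(v)
            assert length == pytest.approx(exp_len, rel=1e-9)
            assert axial_difference(orient, exp_orient) < 1e-9

    def test_ellipse_method_runs(self, rng):
        v = random_star_polygon(rng)
        length, orient = longest_planar_axis(v, method="ellipse")
        assert length > 0 and 0 <= orient < 180


def ellipse_polygon(a, b, n=64, rotate_deg=0.0, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
    r = np.radians(rotate_deg)
    rot = np.array([[np.cos(r), -np.sin(r)], [np.sin(r), np.cos(r)]])
    return xy @ rot.T + np.asarray(center)


class TestElongation:
    def test_circle_is_isotropic(self):
        mag, _ = elongation_nematic(ellipse_polygon(1, 1))
        assert mag == pytest.approx(0.0, abs=1e-9)

    def test_two_to_one_ellipse_is_sixty(self):
        # closed form: 100·(a²−b²)/(a²+b²) = 100·3/5 for a/b = 2
        mag, axis = elongation_nematic(ellipse_polygon(2, 1))
        assert mag == pytest.approx(60.0, abs=0.5)
        assert axial_difference(axis, 0.0) < 1e-6

    def test_rotation_equivariance(self):
        mag0, axis0 = elongation_nematic(ellipse_polygon(2, 1))
        mag37, axis37 = elongation_nematic(ellipse_polygon(2, 1, rotate_deg=37.0))
        assert mag37 == pytest.approx(mag0, rel=1e-9)
        assert axial_difference(axis37, axis0 + 37.0) < 1e-6

    def test_scale_invariance(self, rng):
        v = random_star_polygon(rng)
        mag1, _ = elongation_nematic(v)
        mag2, _ = elongation_nematic(7.3 * v)
        assert mag1 == pytest.approx(mag2, rel=1e-9)

    def test_translation_invariance(self, rng):
        v = random_star_polygon(rng)
        assert elongation_nematic(v)[0] == pytest.approx(
            elongation_nematic(v + np.array([123.0, -45.0]))[0], rel=1e-9
        )


class TestHWRatio:
    def test_arithmetic(self):
        cell = CellShape("c", [(0, 0), (8, 0), (8, 1), (0, 1)], height=10.0)
        width = np.hypot(8, 1)  # longest chord of the rectangle
        assert height_width_ratio(cell) == pytest.approx(10.0 / width)

    def test_unity_when_height_equals_width(self):
        sq = [(0, 0), (1, 0), (1, 1), (0, 1)]
        cell = CellShape("c", sq, height=float(np.sqrt(2)))
        assert height_width_ratio(cell) == pytest.approx(1.0)


def make_fov(cells, bounds=(0, 0, 100, 100), mitotic=()):
    return FieldOfView("f", bounds, cells, set(mitotic))


def square_cell(cid, x, y, size=5.0, height=7.0, neighbors=6):
    poly = [(x, y), (x + size, y), (x + size, y + size), (x, y + size)]
    return CellShape(cid, poly, height=height, neighbor_count=neighbors)


class TestFieldStats:
    def test_density_convention(self):
        # 215 cells in a 1200 μm² field reported per 1200 μm²
        side = np.sqrt(1200.0)
        cells = [square_cell(f"c{i}", (i % 15) * 2, (i // 15) * 2, size=1.0) for i in range(215)]
        fov = make_fov(cells, bounds=(0, 0, side, side))
        assert density(fov, reference_area=1200.0) == pytest.approx(215.0)

    def test_density_is_intensive(self):
        cells = [square_cell(f"c{i}", i * 10.0, 5.0) for i in range(5)]
        fov1 = make_fov(cells, bounds=(0, 0, 50, 50))
        fov2 = make_fov(cells * 4, bounds=(0, 0, 100, 100))  # same pattern density
        # 5 cells / 2500 vs 20 cells / 10000
        assert density(fov1) == pytest.approx(density(fov2))

    def test_density_empty_field(self):
        assert density(make_fov([], bounds=(0, 0, 10, 10))) == 0.0

    def test_density_zero_area(self):
        with pytest.raises(ValueError):
            density(make_fov([], bounds=(0, 0, 0, 10)))

    @pytest.mark.parametrize("n_mit,n_tot,expected", [(5, 250, 2.0), (0, 10, 0.0), (10, 10, 100.0)])
    def test_proliferation(self, n_mit, n_tot, expected):
        cells = [square_cell(f"c{i}", (i % 20) * 6.0, (i // 20) * 6.0) for i in range(n_tot)]
        fov = make_fov(cells, bounds=(0, 0, 200, 200), mitotic=[f"c{i}" for i in range(n_mit)])
        assert proliferation_rate(fov) == pytest.approx(expected)

    def test_proliferation_empty_field(self):
        with pytest.raises(ValueError):
            proliferation_rate(make_fov([]))

    def test_polygon_class_proportions_sum(self):
        cells = [square_cell(f"c{i}", 10 + i * 7.0, 10.0, neighbors=4 + i % 5) for i in range(10)]
        dist = polygon_class_distribution(make_fov(cells))
        assert dist["proportion"].sum() == pytest.approx(1.0)
        assert dist["count"].sum() == 10


class TestThickness:
    def test_solid_band(self):
        mask = np.zeros((40, 100), dtype=bool)
        mask[10:30, :] = True  # 20 px thick, full width
        assert tissue_thickness(mask, px_size=0.5) == pytest.approx(10.0)

    def test_band_with_notch(self):
        mask = np.zeros((40, 100), dtype=bool)
        mask[10:30, :] = True
        mask[10:20, 40:50] = False  # notch of 100 px
        expected = ((20 * 100 - 100) * 0.25) / (100 * 0.5)  # area·px² / (extent·px)
        assert tissue_thickness(mask, px_size=0.5) == pytest.approx(expected)

    def test_translation_invariance(self):
        m1 = np.zeros((40, 100), dtype=bool)
        m1[5:15, 10:60] = True
        m2 = np.roll(m1, 30, axis=1)
        assert tissue_thickness(m1, 0.5) == pytest.approx(tissue_thickness(m2, 0.5))

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            tissue_thickness(np.zeros((5, 5), dtype=bool), 0.5)


class TestNeighborCounts:
    def test_grid_of_squares(self):
        polys = {}
        for i in range(3):
            for j in range(3):
                x, y = i * 5.0, j * 5.0
                polys[f"c{i}{j}"] = np.array(
                    [(x, y), (x + 5, y), (x + 5, y + 5), (x, y + 5)]
                )
        counts = neighbor_counts_from_polygons(polys)
        assert counts["c11"] == 4  # centre cell: 4 edge-sharing neighbours
        assert counts["c00"] == 2  # corner cell


class TestHertwigAlignment:
    def test_axial_difference(self):
        assert axial_difference(10.0, 170.0) == pytest.approx(20.0)
        assert axial_difference(0.0, 90.0) == pytest.approx(90.0)

    def test_uniform_axes_mean_near_45(self, rng):
        # axial difference between two independent uniform axes averages 45°
        cells = {}
        rows = []
        for i in range(600):
            cid = f"c{i}"
            cells[cid] = CellShape(cid, ellipse_polygon(3, 1.5, rotate_deg=rng.uniform(0, 180)), height=6.0)
            rows.append(
                {"mother_id": cid, "angle_deg": 5.0, "category": "planar",
                 "xy_axis_deg": rng.uniform(0, 180)}
            )
        _, summary = hertwig_alignment(pd.DataFrame(rows), cells)
        assert summary["mean_dxy_planar_deg"] == pytest.approx(45.0, abs=4.0)

    def test_unmatched_events_counted(self):
        rows = pd.DataFrame(
            [{"mother_id": "ghost", "angle_deg": 5.0, "category": "planar", "xy_axis_deg": 10.0}]
        )
        per_event, summary = hertwig_alignment(rows, {})
        assert summary["n_unmatched"] == 1 and len(per_event) == 0
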