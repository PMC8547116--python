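"""Projection, least-cost and wind-connectivity distances."""

import itertools

import networkx as nx
import numpy as np
import pytest

import landgen as lg
from landgen.landscape import (
    WIND_EPSILON,
    _bearing_deg,
    haversine_m,
    wind_conductance_graph,
)
from landgen.types import RasterGrid, WindField


def uniform_raster(n_rows, n_cols, cell=0.1, x0=0.0, y0=0.0, values=None):
    vals = np.ones((n_rows, n_cols)) if values is None else np.asarray(values, float)
    return RasterGrid(n_rows, n_cols, x0, y0, cell, -9999.0, vals)


def brute_force_least_cost(r: RasterGrid, src: tuple, dst: tuple) -> float:
    """Exhaustive enumeration of all simple paths on a small raster graph."""
    g = nx.DiGraph()
    valid = ~r.nodata_mask()
    for row, col in itertools.product(range(r.n_rows), range(r.n_cols)):
        if not valid[row, col]:
            continue
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if dr == dc == 0:
                continue
            r2, c2 = row + dr, col + dc
            if 0 <= r2 < r.n_rows and 0 <= c2 < r.n_cols and valid[r2, c2]:
                dist = haversine_m(*r.cell_center(row, col), *r.cell_center(r2, c2))
                cond = (r.values[row, col] + r.values[r2, c2]) / 2
                g.add_edge((row, col), (r2, c2), w=dist / cond)
    best = np.inf
    for path in nx.all_simple_paths(g, src, dst):
        cost = sum(g[u][v]["w"] for u, v in zip(path, path[1:]))
        best = min(best, cost)
    return best


class TestProjection:
    def test_projection_origin(self):
        xy = lg.project_coordinates({"o": (-51.0, 0.0)})
        assert xy["o"] == pytest.approx((500_000.0, 10_000_000.0))

    def test_distance_matches_haversine(self):
        # two coastal populations ~480 km apart
        coords = {"N2": (-49.79809, -29.43227), "S6": (-52.7323, -32.98765)}
        xy = lg.project_coordinates(coords)
        d_proj = float(np.hypot(xy["N2"][0] - xy["S6"][0], xy["N2"][1] - xy["S6"][1]))
        d_hav = float(haversine_m(*coords["N2"], *coords["S6"]))
        assert d_proj == pytest.approx(d_hav, rel=0.005)

    def test_forward_inverse_identity(self):
        coords = {"a": (-52.1, -31.2), "b": (-49.3, -28.8)}
        back = lg.unproject_coordinates(lg.project_coordinates(coords))
        for p in coords:
            assert back[p][0] == pytest.approx(coords[p][0], abs=1e-6)
            assert back[p][1] == pytest.approx(coords[p][1], abs=1e-6)

    def test_far_from_meridian_warns(self):
        with pytest.warns(UserWarning, match="central meridian"):
            lg.project_coordinates({"x": (-70.0, -30.0)})


class TestEuclideanMatrix:
    def test_three_four_five(self):
        xy = {"a": (0.0, 0.0), "b": (3.0, 0.0), "c": (3.0, 4.0)}
        mat = lg.euclidean_distance_matrix(xy)
        assert mat.values[0, 1] == pytest.approx(3.0)
        assert mat.values[1, 2] == pytest.approx(4.0)
        assert mat.values[0, 2] == pytest.approx(5.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        pts = {f"p{i}": tuple(rng.normal(size=2) * 1e4) for i in range(6)}
        shifted = {k: (x + 123.0, y - 456.0) for k, (x, y) in pts.items()}
        np.testing.assert_allclose(
            lg.euclidean_distance_matrix(pts).values,
            lg.euclidean_distance_matrix(shifted).values,
            atol=1e-6,
        )

    def test_coincident_points_zero(self):
        mat = lg.euclidean_distance_matrix({"a": (1.0, 2.0), "b": (1.0, 2.0)})
        assert mat.values[0, 1] == 0.0


class TestResistanceRaster:
    def test_continuous_uniform_one(self):
        mask = uniform_raster(3, 3, values=[[1, 0, 1]] * 3)
        r = lg.build_resistance_raster("continuous", mask)
        assert (r.values == 1.0).all()

    def test_water_bodies_nodata_count(self):
        mask = uniform_raster(3, 3, values=[[1, 0, 1], [1, 0, 1], [1, 1, 1]])
        r = lg.build_resistance_raster("water_bodies", mask)
        assert r.nodata_mask().sum() == (mask.values == 0).sum()

    def test_population_on_water_rejected(self):
        mask = uniform_raster(1, 3, values=[[1, 0, 1]])
        r = lg.build_resistance_raster("water_bodies", mask)
        coords = {"wet": r.cell_center(0, 1), "dry": r.cell_center(0, 0)}
        with pytest.raises(lg.ValidationError, match="wet"):
            lg.least_cost_matrix(r, coords)

    def test_snap_assigns_nearest_land(self):
        mask = uniform_raster(2, 3, values=[[1, 0, 1], [1, 1, 1]])
        r = lg.build_resistance_raster("water_bodies", mask)
        coords = {"wet": r.cell_center(0, 1), "dry": r.cell_center(0, 0)}
        with pytest.warns(UserWarning, match="snapped"):
            mat = lg.least_cost_matrix(r, coords, snap=True)
        assert np.isfinite(mat.values).all()


class TestLeastCost:
    def test_uniform_row_cost_is_cell_distance_times_steps(self):
        r = uniform_raster(5, 10)
        coords = {"a": r.cell_center(2, 1), "b": r.cell_center(2, 8)}
        mat = lg.least_cost_matrix(r, coords)
        expected = haversine_m(*coords["a"], *coords["b"])
        assert mat.values[0, 1] == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("shape,nodata_cells", [
        ((3, 3), [(1, 1)]),
        ((4, 4), [(1, 1), (2, 2)]),
        ((3, 4), []),
        ((4, 4), [(0, 1), (1, 1), (2, 1)]),
    ])
    def test_matches_exhaustive_enumeration(self, shape, nodata_cells):
        vals = np.ones(shape)
        for rc in nodata_cells:
            vals[rc] = -9999.0
        r = uniform_raster(*shape, values=vals)
        src, dst = (0, 0), (shape[0] - 1, shape[1] - 1)
        coords = {"s": r.cell_center(*src), "d": r.cell_center(*dst)}
        mat = lg.least_cost_matrix(r, coords)
        assert mat.values[0, 1] == pytest.approx(
            brute_force_least_cost(r, src, dst), rel=1e-9
        )

    def test_heterogeneous_conductance_against_enumeration(self):
        vals = np.array([
            [1.0, 0.2, 1.0, 1.0],
            [1.0, 0.2, 5.0, 1.0],
            [1.0, 1.0, 1.0, 0.5],
        ])
        r = uniform_raster(3, 4, values=vals)
        coords = {"s": r.cell_center(0, 0), "d": r.cell_center(2, 3)}
        mat = lg.least_cost_matrix(r, coords)
        assert mat.values[0, 1] == pytest.approx(
            brute_force_least_cost(r, (0, 0), (2, 3)), rel=1e-9
        )

    def test_disconnected_pair_infinite(self):
        vals = np.ones((3, 3))
        vals[:, 1] = -9999.0
        r = uniform_raster(3, 3, values=vals)
        coords = {"a": r.cell_center(1, 0), "b": r.cell_center(1, 2)}
        with pytest.warns(UserWarning, match="disconnected"):
            mat = lg.least_cost_matrix(r, coords)
        assert np.isinf(mat.values[0, 1])

    def test_water_model_never_cheaper_than_continuous(self):
        rng = np.random.default_rng(4)
        mask_vals = (rng.random((6, 8)) > 0.25).astype(float)
        mask_vals[0, :] = 1.0  # keep a guaranteed corridor
        mask = uniform_raster(6, 8, values=mask_vals)
        cont = lg.build_resistance_raster("continuous", mask)
        water = lg.build_resistance_raster("water_bodies", mask)
        coords = {"a": mask.cell_center(0, 0), "b": mask.cell_center(0, 7)}
        c1 = lg.least_cost_matrix(cont, coords).values[0, 1]
        c2 = lg.least_cost_matrix(water, coords).values[0, 1]
        assert c2 >= c1 - 1e-9

    def test_uniform_grid_within_discretization_bound(self):
        r = uniform_raster(30, 30, cell=0.05)
        pairs = {
            "a": r.cell_center(25, 2), "b": r.cell_center(3, 20),
            "c": r.cell_center(15, 28),
        }
        mat = lg.least_cost_matrix(r, pairs)
        labels = list(pairs)
        for i, j in itertools.combinations(range(3), 2):
            straight = haversine_m(*pairs[labels[i]], *pairs[labels[j]])
            assert mat.values[i, j] <= straight * 1.085
            assert mat.values[i, j] >= straight * 0.999


class TestWind:
    def _pair_raster(self):
        return uniform_raster(1, 2, cell=0.1)

    def test_tailwind_conductance_equals_speed(self):
        base = self._pair_raster()
        # cells side by side west-east; wind FROM west (270) blows TOWARD 90
        speed = base.like(np.full((1, 2), 5.0))
        direction = base.like(np.full((1, 2), 270.0))
        graph = wind_conductance_graph(speed, direction)
        d = haversine_m(*base.cell_center(0, 0), *base.cell_center(0, 1))
        assert graph[0, 1] == pytest.approx(d / 5.0, rel=1e-6)

    def test_perpendicular_wind_hits_absolute_floor(self):
        base = self._pair_raster()
        speed = base.like(np.full((1, 2), 5.0))
        direction = base.like(np.zeros((1, 2)))  # from north, toward south
        graph = wind_conductance_graph(speed, direction, adverse_fraction=0.0)
        d = haversine_m(*base.cell_center(0, 0), *base.cell_center(0, 1))
        assert graph[0, 1] == pytest.approx(d / WIND_EPSILON, rel=1e-6)

    def test_reversing_wind_transposes_costs(self):
        base = uniform_raster(4, 4, cell=0.1)
        rng = np.random.default_rng(1)
        speed = base.like(np.full((4, 4), 3.0))
        drn = base.like(rng.uniform(0, 360, size=(4, 4)) * 0 + 45.0)
        w1 = WindField([(speed, drn)])
        w2 = WindField([(speed, base.like((drn.values + 180.0) % 360.0))])
        coords = {"a": base.cell_center(0, 0), "b": base.cell_center(3, 3),
                  "c": base.cell_center(0, 3)}
        m1, _ = lg.wind_cost_matrix(w1, coords)
        m2, _ = lg.wind_cost_matrix(w2, coords)
        # exact in the plane; spherical bearings of i->j and j->i differ by a
        # hair more than 180 degrees, hence the loose tolerance
        np.testing.assert_allclose(m1.values, m2.values.T, rtol=1e-4)

    def test_downwind_cheaper_than_upwind(self):
        base = uniform_raster(1, 5, cell=0.1)
        speed = base.like(np.full((1, 5), 6.0))
        direction = base.like(np.full((1, 5), 270.0))  # toward east
        coords = {"w": base.cell_center(0, 0), "e": base.cell_center(0, 4)}
        asym, sym = lg.wind_cost_matrix(WindField([(speed, direction)]), coords)
        assert asym.values[0, 1] < asym.values[1, 0]
        np.testing.assert_allclose(
            sym.values, (asym.values + asym.values.T) / 2, rtol=1e-12
        )

    def test_two_identical_slices_average_is_slice(self):
        base = uniform_raster(1, 3, cell=0.1)
        speed = base.like(np.full((1, 3), 4.0))
        direction = base.like(np.full((1, 3), 90.0))
        coords = {"a": base.cell_center(0, 0), "b": base.cell_center(0, 2)}
        one, _ = lg.wind_cost_matrix(WindField([(speed, direction)]), coords)
        two, _ = lg.wind_cost_matrix(
            WindField([(speed, direction), (speed, direction)]), coords
        )
        np.testing.assert_allclose(one.values, two.values, rtol=1e-12)

    def test_cost_monotone_in_along_bearing_speed(self):
        base = self._pair_raster()
        costs = []
        for s in (1.0, 3.0, 9.0):
            speed = base.like(np.full((1, 2), s))
            direction = base.like(np.full((1, 2), 270.0))
            graph = wind_conductance_graph(speed, direction)
            costs.append(graph[0, 1])
        assert costs[0] > costs[1] > costs[2]

    def test_bearing_convention(self):
        # due north bearing is 0, due east is 90
        assert _bearing_deg(0.0, 0.0, 0.0, 1.0) == pytest.approx(0.0, abs=1e-9)
        assert _bearing_deg(0.0, 0.0, 1.0, 0.0) == pytest.approx(90.0, abs=1e-6)
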