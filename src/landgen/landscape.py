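"""Geographic, resistance and wind-connectivity distances between populations.

Coordinates are projected with a spherical transverse-Mercator (UTM-zone-22S
convention: central meridian -51 degrees, scale 0.9996, false easting 500 km,
southern false northing 10 000 km); straight-line distances are Euclidean in
that plane. Resistance distances come from least-cost paths over a raster
graph with 8-neighbour connectivity: the cost of stepping between adjacent
cells is the great-circle distance between their centres divided by the mean
conductance of the two cells, so a uniform conductance-1 raster yields
metres. Wind connectivity uses a directed graph whose i->j conductance is the
wind-speed component along the i->j bearing (tailwind helps, headwind
blocks), floored at a small positive epsilon.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .types import PairwiseMatrix, PopulationMap, RasterGrid, ValidationError, WindField

EARTH_RADIUS_M = 6_371_008.8

# Transverse Mercator parameters matching the UTM 22S convention
TM_CENTRAL_MERIDIAN = -51.0
TM_SCALE = 0.9996
TM_FALSE_EASTING = 500_000.0
TM_FALSE_NORTHING = 10_000_000.0

#: Absolute conductance floor (m/s) for calm air.
WIND_EPSILON = 1e-4

#: Adverse-wind residual mobility: cross- and head-wind edges keep this
#: fraction of the local wind speed as conductance. Without it the adverse
#: direction of every pair collapses onto the absolute floor, the
#: time-averaged symmetrized matrix degenerates to a multiple of plain path
#: distance, and wind strength carries no information at all.
WIND_ADVERSE_FRACTION = 0.05


# ---------------------------------------------------------------------------
# Projection and straight-line distance
# ---------------------------------------------------------------------------

def project_coordinates(
    m: PopulationMap | Mapping[str, tuple[float, float]],
    central_meridian: float = TM_CENTRAL_MERIDIAN,
) -> dict[str, tuple[float, float]]:
    """Spherical transverse-Mercator forward projection, metres per population."""
    coords = m.coords if isinstance(m, PopulationMap) else dict(m)
    out: dict[str, tuple[float, float]] = {}
    for p, (lon, lat) in coords.items():
        if abs(lon - central_meridian) > 12.0:
            warnings.warn(
                f"population {p!r} is {abs(lon - central_meridian):.1f} deg from "
                "the central meridian; transverse-Mercator distortion grows fast",
                stacklevel=2,
            )
        lam = np.radians(lon - central_meridian)
        phi = np.radians(lat)
        b = np.cos(phi) * np.sin(lam)
        x = TM_FALSE_EASTING + TM_SCALE * EARTH_RADIUS_M * np.arctanh(b)
        y = TM_FALSE_NORTHING + TM_SCALE * EARTH_RADIUS_M * np.arctan2(
            np.tan(phi), np.cos(lam)
        )
        out[p] = (float(x), float(y))
    return out


def unproject_coordinates(
    xy: Mapping[str, tuple[float, float]],
    central_meridian: float = TM_CENTRAL_MERIDIAN,
) -> dict[str, tuple[float, float]]:
    """Inverse of :func:`project_coordinates` (lon, lat degrees)."""
    out = {}
    for p, (x, y) in xy.items():
        xp = (x - TM_FALSE_EASTING) / (TM_SCALE * EARTH_RADIUS_M)
        yp = (y - TM_FALSE_NORTHING) / (TM_SCALE * EARTH_RADIUS_M)
        phi = np.arcsin(np.sin(yp) / np.cosh(xp))
        lam = np.arctan2(np.sinh(xp), np.cos(yp))
        out[p] = (float(np.degrees(lam) + central_meridian), float(np.degrees(phi)))
    return out


def euclidean_distance_matrix(
    xy: Mapping[str, tuple[float, float]], labels: list[str] | None = None
) -> PairwiseMatrix:
    """Pairwise Euclidean distance (metres) between projected coordinates."""
    if labels is None:
        labels = list(xy)
    if len(labels) < 2:
        raise ValidationError("need at least 2 populations for a distance matrix")
    pts = np.array([xy[p] for p in labels], dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    return PairwiseMatrix(list(labels), np.sqrt((diff**2).sum(axis=2)))


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres (array-aware)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))


def _bearing_deg(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Initial great-circle bearing, degrees clockwise from north."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


# ---------------------------------------------------------------------------
# Resistance rasters
# ---------------------------------------------------------------------------

def build_resistance_raster(model: str, land_mask: RasterGrid) -> RasterGrid:
    """Build a conductance raster from a land/water mask.

    ``land_mask`` encodes land as 1 and water as 0 (its nodata cells stay
    nodata). ``model="continuous"`` gives conductance 1 everywhere, water
    included (the null model); ``model="water_bodies"`` keeps land at 1 and
    turns water into nodata, i.e. an absolute barrier.
    """
    mask_nodata = land_mask.nodata_mask()
    vals = land_mask.values
    bad = ~mask_nodata & ~np.isin(vals, (0.0, 1.0))
    if bad.any():
        raise ValidationError("land mask must contain only 0 (water) and 1 (land)")
    if model == "continuous":
        out = np.ones_like(vals)
        out[mask_nodata] = land_mask.nodata_value
    elif model == "water_bodies":
        out = np.where(vals == 1.0, 1.0, land_mask.nodata_value)
        out[mask_nodata] = land_mask.nodata_value
    else:
        raise ValidationError(f"unknown resistance model {model!r}")
    return land_mask.like(out)


# ---------------------------------------------------------------------------
# Raster graphs and least-cost distances
# ---------------------------------------------------------------------------

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _cell_centers(r: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    lon = r.x_llcorner + (np.arange(r.n_cols) + 0.5) * r.cell_size
    lat = r.y_llcorner + (r.n_rows - np.arange(r.n_rows) - 0.5) * r.cell_size
    return lon, lat


def _edge_arrays(r: RasterGrid):
    """Yield (src_rows, src_cols, dst_rows, dst_cols) per 8-neighbour offset,
    restricted to pairs of non-nodata cells."""
    valid = ~r.nodata_mask()
    rows, cols = np.indices(valid.shape)
    for dr, dc in _OFFSETS:
        sr = slice(max(0, -dr), r.n_rows - max(0, dr))
        sc = slice(max(0, -dc), r.n_cols - max(0, dc))
        src_ok = valid[sr, sc]
        dst_ok = valid[
            slice(sr.start + dr, sr.stop + dr), slice(sc.start + dc, sc.stop + dc)
        ]
        ok = src_ok & dst_ok
        yield (
            rows[sr, sc][ok], cols[sr, sc][ok],
            rows[sr, sc][ok] + dr, cols[sr, sc][ok] + dc,
        )


def _node_ids(r: RasterGrid) -> np.ndarray:
    valid = ~r.nodata_mask()
    ids = np.full(valid.shape, -1, dtype=np.int64)
    ids[valid] = np.arange(valid.sum())
    return ids


def _population_nodes(
    r: RasterGrid,
    coords: Mapping[str, tuple[float, float]],
    snap: bool,
) -> dict[str, int]:
    ids = _node_ids(r)
    lon_c, lat_c = _cell_centers(r)
    out = {}
    for p, (lon, lat) in coords.items():
        row, col = r.cell_of(lon, lat)
        if ids[row, col] < 0:
            if not snap:
                raise ValidationError(
                    f"population {p!r} falls on a nodata (barrier) cell; "
                    "pass snap=True to assign the nearest passable cell"
                )
            vr, vc = np.nonzero(ids >= 0)
            d = haversine_m(lon, lat, lon_c[vc], lat_c[vr])
            k = int(np.argmin(d))
            row, col = int(vr[k]), int(vc[k])
            warnings.warn(
                f"population {p!r} snapped to passable cell ({row}, {col}), "
                f"{d[k] / 1000:.1f} km away",
                stacklevel=2,
            )
        out[p] = int(ids[row, col])
    return out


def _graph_from_conductance(r: RasterGrid):
    """Sparse directed cost graph: edge = centre distance / mean conductance."""
    ids = _node_ids(r)
    n_nodes = int((ids >= 0).sum())
    lon_c, lat_c = _cell_centers(r)
    src_list, dst_list, w_list = [], [], []
    for sr, sc, dr_, dc_ in _edge_arrays(r):
        dist = haversine_m(lon_c[sc], lat_c[sr], lon_c[dc_], lat_c[dr_])
        cond = 0.5 * (r.values[sr, sc] + r.values[dr_, dc_])
        ok = cond > 0
        src_list.append(ids[sr, sc][ok])
        dst_list.append(ids[dr_, dc_][ok])
        w_list.append(dist[ok] / cond[ok])
    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    w = np.concatenate(w_list)
    return coo_matrix((w, (src, dst)), shape=(n_nodes, n_nodes)).tocsr()


def least_cost_matrix(
    r: RasterGrid,
    coords: Mapping[str, tuple[float, float]],
    snap: bool = False,
) -> PairwiseMatrix:
    """Least-cost (Dijkstra) distances between population cells.

    ``r`` is a conductance raster (nodata = impassable). Unreachable pairs get
    +inf with a warning. Symmetric for any isotropic conductance raster.
    """
    labels = list(coords)
    nodes = _population_nodes(r, coords, snap)
    graph = _graph_from_conductance(r)
    src = np.array([nodes[p] for p in labels])
    d = dijkstra(graph, directed=True, indices=src)
    vals = d[:, src]
    np.fill_diagonal(vals, 0.0)
    vals = (vals + vals.T) / 2.0  # exact for isotropic graphs; kills float noise
    if np.isinf(vals).any():
        warnings.warn("some population pairs are disconnected (+inf cost)", stacklevel=2)
    return PairwiseMatrix(labels, vals, symmetric=True)


# ---------------------------------------------------------------------------
# Wind connectivity
# ---------------------------------------------------------------------------

def wind_conductance_graph(
    speed: RasterGrid,
    direction: RasterGrid,
    epsilon: float = WIND_EPSILON,
    adverse_fraction: float = WIND_ADVERSE_FRACTION,
):
    """Directed cost graph for one wind slice.

    For neighbours i -> j with bearing phi and wind at i blowing TOWARD theta
    (meteorological direction + 180), conductance is
    ``max(epsilon, adverse_fraction * s_i, s_i * cos(theta - phi))`` and the
    edge cost the centre-to-centre distance divided by it. Tailwind
    facilitates movement in proportion to speed; head- and cross-winds leave
    a residual mobility of ``adverse_fraction`` of the local speed (pass 0 to
    collapse all adverse edges onto the absolute ``epsilon`` floor).
    """
    ids = _node_ids(speed)
    n_nodes = int((ids >= 0).sum())
    lon_c, lat_c = _cell_centers(speed)
    src_list, dst_list, w_list = [], [], []
    for sr, sc, dr_, dc_ in _edge_arrays(speed):
        dist = haversine_m(lon_c[sc], lat_c[sr], lon_c[dc_], lat_c[dr_])
        phi = _bearing_deg(lon_c[sc], lat_c[sr], lon_c[dc_], lat_c[dr_])
        toward = (direction.values[sr, sc] + 180.0) % 360.0
        s = speed.values[sr, sc]
        g = np.maximum(
            epsilon,
            np.maximum(adverse_fraction * s, s * np.cos(np.radians(toward - phi))),
        )
        src_list.append(ids[sr, sc])
        dst_list.append(ids[dr_, dc_])
        w_list.append(dist / g)
    return coo_matrix(
        (np.concatenate(w_list), (np.concatenate(src_list), np.concatenate(dst_list))),
        shape=(n_nodes, n_nodes),
    ).tocsr()


def wind_cost_matrix(
    w: WindField,
    coords: Mapping[str, tuple[float, float]],
    epsilon: float = WIND_EPSILON,
    adverse_fraction: float = WIND_ADVERSE_FRACTION,
    snap: bool = False,
) -> tuple[PairwiseMatrix, PairwiseMatrix]:
    """Time-averaged directed wind cost matrix and its symmetrization.

    Per-slice directed least-cost matrices are averaged arithmetically over
    the time series; the symmetrized matrix (M + M^T) / 2 is what the
    symmetric matrix tests consume. Pairs disconnected in any slice
    contribute +inf and are flagged with a warning.
    """
    labels = list(coords)
    nodes = _population_nodes(w.slices[0][0], coords, snap)
    src = np.array([nodes[p] for p in labels])
    acc = np.zeros((len(labels), len(labels)))
    for speed, direction in w.slices:
        graph = wind_conductance_graph(speed, direction, epsilon, adverse_fraction)
        d = dijkstra(graph, directed=True, indices=src)
        acc += d[:, src]
    acc /= w.n_slices
    np.fill_diagonal(acc, 0.0)
    if np.isinf(acc).any():
        warnings.warn("some pairs disconnected in at least one wind slice", stacklevel=2)
    asym = PairwiseMatrix(labels, acc, symmetric=False)
    return asym, asym.symmetrized()
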