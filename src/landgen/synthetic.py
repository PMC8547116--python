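"""Synthetic genotypes, landscapes, wind fields and climate surfaces.

Every downstream stage is verified against data generated here under known
ground truth. Genotypes come from a forward-time drift-migration recursion on
population allele frequencies (deterministic migration mixing followed by
binomial/multinomial resampling of 2N gene copies per deme), then
Hardy-Weinberg sampling of diploid individuals within demes. Landscapes are a
coastal strip raster pierced by an elongated lagoon, a directional wind field
and a climate surface, emulating a linear coastal plain with large water
bodies, persistent NE spring winds and a rainfall-seasonality gradient.

Scenarios
---------
``panmixia``            one gene pool sampled by every population.
``island``              symmetric migration between every deme pair.
``stepping_stone``      chain migration between coastal neighbours (IBD).
``barrier``             chain with one nearly severed link where the lagoon
                        cuts the strip.
``wind_biased``         chain whose migration intensity follows the local
                        wind speed (asymmetric, downwind-facilitated).
``environment_driven``  migration follows environmental similarity rather
                        than distance (IBE).
``study_shaped``        15 populations with the coastal study's sample sizes
                        and coordinates, 10 loci with 7-17 alleles each.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    GenotypeMatrix,
    PairwiseMatrix,
    PopulationMap,
    RasterGrid,
    ValidationError,
    WindField,
)

SCENARIO_NAMES = (
    "panmixia", "island", "stepping_stone", "barrier",
    "wind_biased", "environment_driven", "study_shaped",
)

# Sample sizes and coordinates of the 15-population coastal dataset the
# study-shaped scenario emulates (n = 253 individuals in total).
STUDY_POPULATIONS: dict[str, tuple[int, float, float]] = {
    "I1": (4, -55.10077, -29.58307),
    "I2": (10, -54.85375, -29.8947),
    "I3": (9, -54.90852, -29.85478),
    "W1": (27, -51.20255, -30.40754),
    "W2": (4, -51.49195, -30.90082),
    "W3": (23, -52.16478, -31.70757),
    "N1": (10, -48.76501, -28.45991),
    "N2": (23, -49.79809, -29.43227),
    "N3": (37, -50.42936, -29.89291),
    "S1": (3, -50.73934, -30.93746),
    "S2": (13, -50.90112, -31.10909),
    "S3": (12, -51.42576, -31.66673),
    "S4": (11, -52.03612, -32.02393),
    "S5": (26, -52.54661, -32.52396),
    "S6": (41, -52.7323, -32.98765),
}


@dataclass
class Scenario:
    """Parameters of one simulation scenario; the seed is mandatory."""

    name: str
    seed: int
    n_pops: int = 8
    sizes: list[int] | None = None  # sampled individuals per population
    n_loci: int = 10
    alleles_per_locus: tuple[int, int] = (7, 17)  # uniform draw bounds
    deme_size: int = 200  # diploid N per deme in the forward simulation
    migration: float = 0.05  # total emigration fraction per generation
    generations: int = 200
    missing_rate: float = 0.02
    barrier_link: int | None = None  # chain link index severed under "barrier"
    wind_from_deg: float = 45.0  # meteorological: wind blows FROM the NE
    wind_speed: float = 5.0  # mean speed m/s
    strip_sw: tuple[float, float] = (-53.0, -33.0)  # lon, lat of SW strip end
    strip_ne: tuple[float, float] = (-48.0, -28.0)
    cell_size: float = 0.09
    climate_noise: float = 0.01  # sd of cell noise on the climate surface
    env_values: list[float] | None = None  # per-population environment

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValidationError(f"unknown scenario {self.name!r}")
        if not (0 <= self.migration <= 1):
            raise ValidationError("migration must be in [0, 1]")
        if self.sizes is not None and any(s < 1 for s in self.sizes):
            raise ValidationError("population sizes must be >= 1")


def make_scenario(name: str, seed: int, **overrides) -> Scenario:
    """Scenario with per-name defaults; keyword overrides win."""
    defaults: dict = {}
    if name == "study_shaped":
        defaults.update(
            n_pops=15,
            sizes=[v[0] for v in STUDY_POPULATIONS.values()],
            migration=0.02,
            generations=300,
        )
    elif name == "barrier":
        defaults.update(barrier_link=None)  # middle link by default
    elif name == "environment_driven":
        defaults.update(migration=0.1)
    elif name == "panmixia":
        defaults.update(migration=1.0)
    sc = Scenario(name=name, seed=seed, **{**defaults, **overrides})
    if sc.sizes is None:
        sc = replace(sc, sizes=[20] * sc.n_pops)
    if len(sc.sizes) != sc.n_pops:
        raise ValidationError("len(sizes) != n_pops")
    return sc


# ---------------------------------------------------------------------------
# Population geometry and environment
# ---------------------------------------------------------------------------

def population_positions(s: Scenario) -> dict[str, tuple[float, float]]:
    """Population lon/lat along the coastal strip (or the study's table)."""
    if s.name == "study_shaped":
        return {p: (lon, lat) for p, (_, lon, lat) in STUDY_POPULATIONS.items()}
    t = np.linspace(0.05, 0.95, s.n_pops)
    lon = s.strip_sw[0] + t * (s.strip_ne[0] - s.strip_sw[0])
    lat = s.strip_sw[1] + t * (s.strip_ne[1] - s.strip_sw[1])
    return {f"pop_{i + 1}": (float(lon[i]), float(lat[i])) for i in range(s.n_pops)}


def environment_values(s: Scenario) -> np.ndarray:
    """Per-population environment (e.g. precipitation seasonality).

    ``environment_driven`` uses an alternating high/low pattern so that
    environmental dissimilarity is nearly orthogonal to along-coast distance;
    other scenarios get a smooth along-coast gradient.
    """
    if s.env_values is not None:
        return np.asarray(s.env_values, dtype=float)
    if s.name == "environment_driven":
        return np.array([10.0 if i % 2 else 0.0 for i in range(s.n_pops)])
    return np.linspace(0.0, 10.0, s.n_pops)


def wind_speed_profile(s: Scenario) -> np.ndarray:
    """Mean along-coast wind speed per chain segment (n_pops - 1 values).

    ``wind_biased`` alternates strong and weak wind corridors so the wind
    cost matrix carries information that plain distance does not.
    """
    k = s.n_pops - 1
    if s.name == "wind_biased":
        return np.where(np.arange(k) % 2 == 0, s.wind_speed * 1.8, s.wind_speed * 0.2)
    return np.full(k, s.wind_speed)


# ---------------------------------------------------------------------------
# Migration matrices
# ---------------------------------------------------------------------------

def chain_order(s: Scenario) -> np.ndarray:
    """Deme indices ordered along the coast axis (chain neighbour order)."""
    pos = list(population_positions(s).values())
    d_lon = s.strip_ne[0] - s.strip_sw[0]
    d_lat = s.strip_ne[1] - s.strip_sw[1]
    t = [
        (lon - s.strip_sw[0]) * d_lon + (lat - s.strip_sw[1]) * d_lat
        for lon, lat in pos
    ]
    return np.argsort(np.array(t), kind="stable")


def migration_matrix(s: Scenario) -> np.ndarray:
    """Row-stochastic mixing matrix M: deme i's next gene pool is
    ``sum_j M[i, j] * p_j`` with ``M[i, i] = 1 - total immigration``."""
    n, m = s.n_pops, s.migration
    M = np.zeros((n, n))
    if s.name == "panmixia":
        M[:] = 1.0 / n
        return M
    if s.name == "island":
        off = m / (n - 1)
        M[:] = off
        np.fill_diagonal(M, 1.0 - m)
        return M
    if s.name == "environment_driven":
        env = environment_values(s)
        sim = np.exp(-np.abs(env[:, None] - env[None, :]) / 2.0)
        np.fill_diagonal(sim, 0.0)
        M = sim / sim.sum(axis=1, keepdims=True) * m
        np.fill_diagonal(M, 1.0 - m)
        return M
    # chain scenarios: stepping_stone, barrier, wind_biased, study_shaped
    order = chain_order(s)
    if s.name == "wind_biased":
        speeds = wind_speed_profile(s)
        rel = speeds / speeds.max()
        for i in range(n - 1):
            a, b = order[i], order[i + 1]
            down = m * rel[i]  # wind-facilitated direction along the chain
            up = 0.25 * down
            M[b, a] = down  # deme b receives from a
            M[a, b] = up
    else:
        for i in range(n - 1):
            a, b = order[i], order[i + 1]
            M[a, b] = M[b, a] = m / 2.0
        if s.name == "barrier":
            link = s.barrier_link if s.barrier_link is not None else (n - 1) // 2
            a, b = order[link], order[link + 1]
            M[a, b] = M[b, a] = m * 1e-3
    totals = M.sum(axis=1)
    if (totals > 1).any():
        raise ValidationError("total immigration into a deme exceeds 1")
    np.fill_diagonal(M, 1.0 - totals)
    return M


# ---------------------------------------------------------------------------
# Forward allele-frequency simulation
# ---------------------------------------------------------------------------

def simulate_allele_frequencies(
    s: Scenario, return_trajectory: bool = False
) -> list[np.ndarray]:
    """Forward drift-migration simulation.

    Returns, per locus, an (n_pops, n_alleles) frequency array at the final
    generation (or a list of per-generation arrays with
    ``return_trajectory=True``). Each generation applies deterministic
    migration mixing then multinomial resampling of 2N gene copies per deme.
    """
    rng = np.random.default_rng(np.random.SeedSequence([s.seed, 0x51]))
    M = migration_matrix(s)
    lo, hi = s.alleles_per_locus
    out = []
    for _ in range(s.n_loci):
        k = int(rng.integers(lo, hi + 1))
        ancestral = rng.dirichlet(np.full(k, 5.0))
        p = np.tile(ancestral, (s.n_pops, 1))
        traj = [p.copy()]
        for _gen in range(s.generations):
            p = M @ p
            for i in range(s.n_pops):
                draws = rng.multinomial(2 * s.deme_size, p[i])
                p[i] = draws / (2 * s.deme_size)
            if return_trajectory:
                traj.append(p.copy())
        out.append(traj if return_trajectory else p)
    return out


def sample_genotypes(
    freqs: list[np.ndarray],
    sizes: list[int],
    missing_rate: float,
    seed: int,
    coords: dict[str, tuple[float, float]] | None = None,
    pop_ids: list[str] | None = None,
    allele_size_base: int = 100,
    repeat_unit: int = 2,
) -> tuple[GenotypeMatrix, PopulationMap]:
    """Hardy-Weinberg sampling of diploid genotypes from deme frequencies.

    Allele index a at any locus maps to size ``allele_size_base +
    repeat_unit * a`` (a 2-bp ladder by default). Calls are dropped to
    missing independently at ``missing_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6E]))
    n_pops = freqs[0].shape[0]
    if pop_ids is None:
        pop_ids = [f"pop_{i + 1}" for i in range(n_pops)]
    if coords is None:
        coords = {p: (float(-53 + 5 * i / max(1, n_pops - 1)),
                      float(-33 + 5 * i / max(1, n_pops - 1)))
                  for i, p in enumerate(pop_ids)}
    ids: list[str] = []
    assignment: dict[str, str] = {}
    rows = []
    for i, p in enumerate(pop_ids):
        for ind in range(sizes[i]):
            ind_id = f"{p}_{ind + 1}"
            ids.append(ind_id)
            assignment[ind_id] = p
            calls = []
            for locus_freqs in freqs:
                pf = locus_freqs[i]
                a = rng.choice(len(pf), size=2, p=pf)
                if rng.random() < missing_rate:
                    calls.append((0, 0))
                else:
                    calls.append((
                        allele_size_base + repeat_unit * int(a[0]),
                        allele_size_base + repeat_unit * int(a[1]),
                    ))
            rows.append(calls)
    g = GenotypeMatrix(
        ids, [f"loc_{j + 1}" for j in range(len(freqs))],
        np.array(rows, dtype=np.int64),
    )
    m = PopulationMap(pop_ids, assignment, {p: coords[p] for p in pop_ids})
    return g, m


def simulate_dataset(s: Scenario) -> tuple[GenotypeMatrix, PopulationMap]:
    """Convenience: frequencies -> genotypes for a scenario."""
    freqs = simulate_allele_frequencies(s)
    coords = population_positions(s)
    return sample_genotypes(
        freqs, list(s.sizes), s.missing_rate, s.seed,
        coords=coords, pop_ids=list(coords),
    )


# ---------------------------------------------------------------------------
# Landscape, wind and climate rasters
# ---------------------------------------------------------------------------

def _strip_grid(s: Scenario) -> RasterGrid:
    # cover the strip axis and every population (study-shaped has inland
    # populations well off the coast axis), with a half-degree margin
    lons = [s.strip_sw[0], s.strip_ne[0]]
    lats = [s.strip_sw[1], s.strip_ne[1]]
    for lon, lat in population_positions(s).values():
        lons.append(lon)
        lats.append(lat)
    lon_min, lon_max = min(lons) - 0.5, max(lons) + 0.5
    lat_min, lat_max = min(lats) - 0.5, max(lats) + 0.5
    n_cols = int(np.ceil((lon_max - lon_min) / s.cell_size))
    n_rows = int(np.ceil((lat_max - lat_min) / s.cell_size))
    return RasterGrid(
        n_rows, n_cols, lon_min, lat_min, s.cell_size, -9999.0,
        np.ones((n_rows, n_cols)),
    )


def simulate_landscape(
    s: Scenario, n_wind_slices: int = 8
) -> tuple[RasterGrid, WindField, RasterGrid]:
    """Land/water mask, wind field and climate surface for a scenario.

    The mask is an all-land strip with an elongated interior lagoon running
    parallel to the coast; under the ``barrier`` scenario the lagoon widens
    into a channel that fully severs the strip at the barrier link. Wind
    slices share a mean bearing (meteorological ``wind_from_deg``) with
    per-slice direction and speed noise; the wind-biased speed profile is
    painted along the coast axis. The climate surface interpolates the
    per-population environment values along the same axis, plus noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([s.seed, 0x1A]))
    base = _strip_grid(s)
    n_rows, n_cols = base.n_rows, base.n_cols
    lon = base.x_llcorner + (np.arange(n_cols) + 0.5) * base.cell_size
    lat = base.y_llcorner + (n_rows - np.arange(n_rows) - 0.5) * base.cell_size
    LON, LAT = np.meshgrid(lon, lat)

    # coast axis parameter t in [0, 1], SW end -> NE end
    d_lon = s.strip_ne[0] - s.strip_sw[0]
    d_lat = s.strip_ne[1] - s.strip_sw[1]
    norm2 = d_lon**2 + d_lat**2
    T = ((LON - s.strip_sw[0]) * d_lon + (LAT - s.strip_sw[1]) * d_lat) / norm2
    # signed offset from the coast axis, in degrees (positive = inland/NW)
    OFF = ((LON - s.strip_sw[0]) * -d_lat + (LAT - s.strip_sw[1]) * d_lon) / np.sqrt(norm2)

    mask = np.ones((n_rows, n_cols))
    if s.name == "barrier":
        # channel perpendicular to the coast, centred at the severed link
        link = s.barrier_link if s.barrier_link is not None else (s.n_pops - 2) // 2
        t_pops = np.linspace(0.05, 0.95, s.n_pops)
        t_cut = (t_pops[link] + t_pops[link + 1]) / 2
        mask[np.abs(T - t_cut) < 0.02] = 0.0
    else:
        # interior lagoon: elongated along the coast, offset inland
        lagoon = (np.abs(OFF - 0.35) < 0.15) & (T > 0.3) & (T < 0.7)
        mask[lagoon] = 0.0
        # sampling sites are lakeside, never on water: keep population cells land
        for lon_p, lat_p in population_positions(s).values():
            row, col = base.cell_of(lon_p, lat_p)
            mask[row, col] = 1.0
    land_mask = base.like(mask)

    # wind: per-slice speed and direction rasters
    seg_speed = wind_speed_profile(s)
    seg_edges = np.linspace(0.0, 1.0, s.n_pops)
    seg_idx = np.clip(np.searchsorted(seg_edges, T, side="right") - 1, 0, len(seg_speed) - 1)
    mean_speed = seg_speed[seg_idx]
    slices = []
    for _ in range(n_wind_slices):
        spd = np.clip(mean_speed + rng.normal(0, 0.3, size=mask.shape), 0.05, None)
        drn = (s.wind_from_deg + rng.normal(0, 5.0, size=mask.shape)) % 360.0
        slices.append((base.like(spd), base.like(drn)))
    wind = WindField(slices)

    env = environment_values(s)
    t_pops = np.linspace(0.05, 0.95, s.n_pops)
    climate_vals = np.interp(np.clip(T, 0, 1), t_pops, env)
    if s.climate_noise > 0:
        climate_vals = climate_vals + rng.normal(0, s.climate_noise, size=mask.shape)
    climate = base.like(climate_vals)
    return land_mask, wind, climate
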