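"""Core data containers shared by every analysis stage.

The package revolves around four small value types:

``GenotypeMatrix``
    Diploid codominant calls (allele sizes in base pairs) for individuals x loci.
``PopulationMap``
    Individual -> population assignment plus population longitude/latitude.
``PairwiseMatrix``
    A labelled square population x population matrix (genetic, geographic,
    resistance, wind or climate distances).
``RasterGrid`` / ``WindField``
    Georeferenced cell grids (ESRI ASCII convention: row 0 is the northernmost
    row) and a time series of (speed, direction) raster pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Sentinel for a missing allele call. Allele sizes are strictly positive, so
#: zero is unambiguous.
MISSING = 0


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


@dataclass
class GenotypeMatrix:
    """Diploid allele-size calls for ``n_individuals x n_loci``.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` with integer allele
    sizes in base pairs; both entries of a call are ``MISSING`` or both are
    positive.
    """

    individual_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, l = len(self.individual_ids), len(self.locus_names)
        if self.calls.shape != (n, l, 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} != ({n}, {l}, 2)"
            )
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual ids")
        if len(set(self.locus_names)) != l:
            raise ValidationError("duplicate locus names")
        if (self.calls < 0).any():
            raise ValidationError("negative allele size")
        half_missing = (self.calls == MISSING).sum(axis=2) == 1
        if half_missing.any():
            i, j = np.argwhere(half_missing)[0]
            raise ValidationError(
                "half-missing call at individual "
                f"{self.individual_ids[i]!r}, locus {self.locus_names[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is missing."""
        return (self.calls == MISSING).all(axis=2)

    def subset(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            list(self.locus_names),
            self.calls[idx],
        )


@dataclass
class PopulationMap:
    """Population membership and coordinates (longitude, latitude, degrees)."""

    population_ids: list[str]
    assignment: dict[str, str]
    coords: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if len(set(self.population_ids)) != len(self.population_ids):
            raise ValidationError("duplicate population ids")
        pops = set(self.population_ids)
        bad = {p for p in self.assignment.values() if p not in pops}
        if bad:
            raise ValidationError(f"assignment references unknown populations: {sorted(bad)}")
        empty = pops - set(self.assignment.values())
        if empty:
            raise ValidationError(f"empty populations: {sorted(empty)}")
        for p, (lon, lat) in self.coords.items():
            if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
                raise ValidationError(f"coordinates out of range for {p!r}: ({lon}, {lat})")

    @property
    def n_populations(self) -> int:
        return len(self.population_ids)

    def members(self, population_id: str) -> list[str]:
        return [i for i, p in self.assignment.items() if p == population_id]

    def sizes(self) -> dict[str, int]:
        out = {p: 0 for p in self.population_ids}
        for p in self.assignment.values():
            out[p] += 1
        return out

    def indices(self, g: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Row indices into ``g`` for each population, in map order."""
        pos = {ind: i for i, ind in enumerate(g.individual_ids)}
        missing = [i for i in self.assignment if i not in pos]
        if missing:
            raise ValidationError(
                f"individuals in map absent from genotypes: {missing[:5]}"
            )
        out: dict[str, np.ndarray] = {}
        for p in self.population_ids:
            out[p] = np.array([pos[i] for i in g.individual_ids
                               if self.assignment.get(i) == p], dtype=int)
        return out


@dataclass
class PairwiseMatrix:
    """Square labelled matrix of pairwise quantities between populations."""

    labels: list[str]
    values: np.ndarray
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValidationError(f"matrix shape {self.values.shape} != ({k}, {k})")
        if self.symmetric and not np.array_equal(
            self.values, self.values.T, equal_nan=True
        ):
            raise ValidationError("matrix flagged symmetric but values are not")

    @property
    def n(self) -> int:
        return len(self.labels)

    def tri(self) -> np.ndarray:
        """Lower-triangle (i > j) vector in row-major pair order."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def reorder(self, labels: Sequence[str]) -> "PairwiseMatrix":
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)], self.symmetric)

    def symmetrized(self) -> "PairwiseMatrix":
        return PairwiseMatrix(list(self.labels), (self.values + self.values.T) / 2.0, True)

    @staticmethod
    def from_pairs(labels: Sequence[str], fill: float = 0.0) -> "PairwiseMatrix":
        k = len(labels)
        return PairwiseMatrix(list(labels), np.full((k, k), fill, dtype=float))


@dataclass
class RasterGrid:
    """ESRI-ASCII-style grid: row 0 is the NORTH-most row."""

    n_rows: int
    n_cols: int
    x_llcorner: float
    y_llcorner: float
    cell_size: float
    nodata_value: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be positive")
        if self.values.shape != (self.n_rows, self.n_cols):
            raise ValidationError(
                f"values shape {self.values.shape} != ({self.n_rows}, {self.n_cols})"
            )

    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata_value

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell centre; row 0 = north."""
        lon = self.x_llcorner + (col + 0.5) * self.cell_size
        lat = self.y_llcorner + (self.n_rows - row - 0.5) * self.cell_size
        return lon, lat

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        col = int(np.floor((lon - self.x_llcorner) / self.cell_size))
        row = self.n_rows - 1 - int(np.floor((lat - self.y_llcorner) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValidationError(f"point ({lon}, {lat}) outside raster extent")
        return row, col

    def like(self, values: np.ndarray, nodata_value: float | None = None) -> "RasterGrid":
        return RasterGrid(
            self.n_rows, self.n_cols, self.x_llcorner, self.y_llcorner,
            self.cell_size,
            self.nodata_value if nodata_value is None else nodata_value,
            values,
        )

    def value_at(self, lon: float, lat: float) -> float:
        r, c = self.cell_of(lon, lat)
        return float(self.values[r, c])


@dataclass
class WindField:
    """Time series of (speed m/s, meteorological direction degrees) rasters.

    Direction is the compass bearing the wind blows FROM (GFS convention);
    downstream code converts to the blowing-toward bearing with +180 degrees.
    """

    slices: list[tuple[RasterGrid, RasterGrid]]

    def __post_init__(self) -> None:
        if not self.slices:
            raise ValidationError("wind field needs at least one time slice")
        ref = self.slices[0][0]
        geom = (ref.n_rows, ref.n_cols, ref.x_llcorner, ref.y_llcorner, ref.cell_size)
        for speed, direction in self.slices:
            for r in (speed, direction):
                if (r.n_rows, r.n_cols, r.x_llcorner, r.y_llcorner, r.cell_size) != geom:
                    raise ValidationError("wind slices do not share grid geometry")
            if (speed.values[~speed.nodata_mask()] < 0).any():
                raise ValidationError("negative wind speed")
            d = direction.values[~direction.nodata_mask()]
            if ((d < 0) | (d >= 360)).any():
                raise ValidationError("wind direction outside [0, 360)")

    @property
    def n_slices(self) -> int:
        return len(self.slices)
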