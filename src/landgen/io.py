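"""Readers and writers for the formats the pipeline consumes.

Supported formats:

* GenePop text files (3-digit-per-allele dialect) for diploid microsatellite
  genotypes;
* ESRI ASCII grids (``.asc``) for rasters;
* labelled CSV for pairwise matrices and population coordinates.

All parsers validate against the container invariants in :mod:`landgen.types`
before returning, so downstream statistics can assume well-formed inputs.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    MISSING,
    GenotypeMatrix,
    PairwiseMatrix,
    PopulationMap,
    RasterGrid,
    ValidationError,
)


class ParseError(ValueError):
    """Raised for malformed input files; the message names the offending line."""


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def _parse_call(tok: str, lineno: int) -> tuple[int, int]:
    if len(tok) != 6 or not tok.isdigit():
        if tok.isdigit() and len(tok) in (2, 4):
            raise ParseError(
                f"line {lineno}: 2-digit-per-allele GenePop coding is not "
                f"supported (field {tok!r}); re-export with 3-digit alleles"
            )
        raise ParseError(
            f"line {lineno}: malformed allele field {tok!r} "
            "(expected 6 digits, 3 per allele)"
        )
    a1, a2 = int(tok[:3]), int(tok[3:])
    if (a1 == 0) != (a2 == 0):
        raise ParseError(f"line {lineno}: half-missing call {tok!r}")
    return a1, a2


def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, PopulationMap]:
    """Parse a GenePop file (3-digit allele coding).

    Populations are named ``pop_1`` ... ``pop_k`` in file order; GenePop files
    carry no coordinates, so the returned map has an empty ``coords`` dict
    (attach coordinates with :func:`read_population_csv`).
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError("file too short to be GenePop")
    # Title line, then locus names: either comma-separated on one line or one
    # per line, until the first POP marker.
    cursor = 1
    locus_names: list[str] = []
    while cursor < len(lines) and lines[cursor].strip().upper() != "POP":
        part = lines[cursor].strip()
        if part:
            locus_names.extend(t.strip() for t in part.split(",") if t.strip())
        cursor += 1
    if cursor == len(lines):
        raise ParseError("no POP separator found")
    if not locus_names:
        raise ParseError("no locus names before first POP")

    ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_of: list[int] = []
    n_pops = 0
    for lineno, raw in enumerate(lines[cursor:], start=cursor + 1):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            n_pops += 1
            continue
        if "," not in line:
            raise ParseError(f"line {lineno}: expected 'id , alleles...' row")
        name, _, rest = line.partition(",")
        toks = rest.split()
        if len(toks) != len(locus_names):
            raise ParseError(
                f"line {lineno}: {len(toks)} allele fields for "
                f"{len(locus_names)} loci"
            )
        ids.append(name.strip())
        rows.append([_parse_call(t, lineno) for t in toks])
        pop_of.append(n_pops - 1)

    if not ids:
        raise ParseError("no individuals parsed")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate individual ids: {dupes}")

    calls = np.array(rows, dtype=np.int64)
    g = GenotypeMatrix(ids, locus_names, calls)
    pop_ids = [f"pop_{i + 1}" for i in range(n_pops)]
    assignment = {ind: pop_ids[p] for ind, p in zip(ids, pop_of)}
    m = PopulationMap(pop_ids, assignment, {})
    return g, m


def write_genepop(
    g: GenotypeMatrix, m: PopulationMap, path: str | Path, title: str = "landgen export"
) -> None:
    """Write genotypes in GenePop 3-digit coding, one POP block per population."""
    if (g.calls > 999).any():
        raise ValidationError("allele size exceeds 999: cannot use 3-digit coding")
    idx = m.indices(g)
    out = [title]
    out.extend(g.locus_names)
    for p in m.population_ids:
        out.append("POP")
        for i in idx[p]:
            fields = " ".join(
                f"{g.calls[i, l, 0]:03d}{g.calls[i, l, 1]:03d}"
                for l in range(g.n_loci)
            )
            out.append(f"{g.individual_ids[i]} , {fields}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# ESRI ASCII raster
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_ascii_raster(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid; the first data row is the northernmost."""
    text = Path(path).read_text().split("\n")
    header: dict[str, float] = {}
    cursor = 0
    for cursor, line in enumerate(text):
        toks = line.split()
        if len(toks) == 2 and toks[0].lower() in _HEADER_KEYS:
            header[toks[0].lower()] = float(toks[1])
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ParseError(f"missing header field {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    try:
        values = np.array([float(t) for t in " ".join(text[cursor:]).split()])
    except ValueError as exc:
        raise ParseError(f"bad raster values: {exc}") from exc
    if values.size != n_rows * n_cols:
        raise ParseError(
            f"expected {n_rows * n_cols} values, found {values.size}"
        )
    return RasterGrid(
        n_rows, n_cols, header["xllcorner"], header["yllcorner"],
        header["cellsize"], nodata, values.reshape(n_rows, n_cols),
    )


def write_ascii_raster(r: RasterGrid, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write(f"ncols {r.n_cols}\n")
    buf.write(f"nrows {r.n_rows}\n")
    buf.write(f"xllcorner {r.x_llcorner!r}\n")
    buf.write(f"yllcorner {r.y_llcorner!r}\n")
    buf.write(f"cellsize {r.cell_size!r}\n")
    buf.write(f"NODATA_value {r.nodata_value!r}\n")
    for row in r.values:
        buf.write(" ".join(repr(float(v)) for v in row) + "\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Pairwise matrices and coordinates (CSV)
# ---------------------------------------------------------------------------

def write_pairwise_csv(p: PairwiseMatrix, path: str | Path) -> None:
    """Labelled CSV; asymmetric matrices carry a ``# asymmetric`` flag line."""
    with open(path, "w") as fh:
        if not p.symmetric:
            fh.write("# asymmetric\n")
        df = pd.DataFrame(p.values, index=p.labels, columns=p.labels)
        df.to_csv(fh, float_format="%.12g")


def read_pairwise_csv(path: str | Path) -> PairwiseMatrix:
    text = Path(path).read_text()
    symmetric = True
    if text.startswith("# asymmetric"):
        symmetric = False
        text = text.split("\n", 1)[1]
    df = pd.read_csv(_io.StringIO(text), index_col=0)
    labels = [str(l) for l in df.index]
    if labels != [str(c) for c in df.columns]:
        raise ParseError("row and column labels differ")
    return PairwiseMatrix(labels, df.to_numpy(dtype=float), symmetric)


def read_population_csv(path: str | Path) -> dict[str, tuple[float, float]]:
    """CSV with columns ``population, longitude, latitude`` -> coords dict."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for need in ("population", "longitude", "latitude"):
        if need not in cols:
            raise ParseError(f"coordinate CSV missing column {need!r}")
    return {
        str(row[cols["population"]]): (
            float(row[cols["longitude"]]), float(row[cols["latitude"]])
        )
        for _, row in df.iterrows()
    }


def write_population_csv(coords: dict[str, tuple[float, float]], path: str | Path) -> None:
    pd.DataFrame(
        [(p, lon, lat) for p, (lon, lat) in coords.items()],
        columns=["population", "longitude", "latitude"],
    ).to_csv(path, index=False)


def attach_coords(m: PopulationMap, coords: dict[str, tuple[float, float]]) -> PopulationMap:
    missing = [p for p in m.population_ids if p not in coords]
    if missing:
        raise ValidationError(f"no coordinates for populations: {missing}")
    return PopulationMap(
        list(m.population_ids), dict(m.assignment),
        {p: coords[p] for p in m.population_ids},
    )


# ---------------------------------------------------------------------------
# Dataset validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    population_sizes: dict[str, int]
    locus_missingness: dict[str, float]
    monomorphic_loci: list[str]
    warnings: list[str] = field(default_factory=list)


def validate_dataset(g: GenotypeMatrix, m: PopulationMap) -> ValidationReport:
    """Structural check of a genotype/population pair.

    Raises on structural violations (unassigned individuals, empty
    populations); data-quality oddities (all-missing or monomorphic loci) are
    reported as warnings.
    """
    assigned = set(m.assignment)
    stray = [i for i in g.individual_ids if i not in assigned]
    if stray:
        raise ValidationError(f"individuals absent from population map: {stray[:10]}")
    m.indices(g)  # raises if the map names individuals not genotyped

    missing = g.missing_mask()
    locus_missingness = {
        loc: float(missing[:, j].mean()) for j, loc in enumerate(g.locus_names)
    }
    monomorphic: list[str] = []
    warnings: list[str] = []
    for j, loc in enumerate(g.locus_names):
        alleles = g.calls[:, j, :][g.calls[:, j, :] != MISSING]
        if alleles.size == 0:
            monomorphic.append(loc)
            warnings.append(f"locus {loc!r}: all calls missing (uninformative)")
        elif np.unique(alleles).size == 1:
            monomorphic.append(loc)
            warnings.append(f"locus {loc!r}: monomorphic")
    return ValidationReport(m.sizes(), locus_missingness, monomorphic, warnings)
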