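"""File I/O for all pipeline formats.

Text formats only: occurrences / flowering / crosses CSV, pairwise D-matrix
CSV, long-format barrier and cascade CSVs, paired total-RI matrix CSV, ESRI
ASCII grids (one ``.asc`` file per environmental layer), Newick trees, and
JSON reports.  Readers validate schemas and address errors by row and
column.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import EnvGrid, OccurrenceSet, SuitabilitySurface
from .synth import CrossRecord, FloweringRecord

NODATA_DEFAULT = -9999.0

OCCURRENCE_COLUMNS = ["species", "lon", "lat", "role"]
FLOWERING_COLUMNS = ["record_id", "species", "onset_day", "source", "year", "block"]
CROSS_COLUMNS = [
    "acceptor", "donor", "treatment", "n_pollinations", "n_fruits",
    "n_seeds_total", "n_seeds_viable", "n_pollen_total", "n_pollen_germinated",
]


class SchemaError(ValueError):
    """Raised for malformed tables or grids, naming the offending location."""


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}; found {list(df.columns)}")


# ---------------------------------------------------------------- ESRI ASCII

def write_ascii_grid(path, values: np.ndarray, extent, cellsize: float,
                     nodata: float = NODATA_DEFAULT) -> None:
    """Write one layer as an ESRI ASCII grid (.asc).  NaN cells become NODATA."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    lon_min, _, lat_min, _ = extent
    out = np.where(np.isnan(values), nodata, values)
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {lon_min}\n"
        f"yllcorner {lat_min}\n"
        f"cellsize {cellsize}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float, float, float], float]:
    """Read an ESRI ASCII grid.  Returns (values with NaN at NODATA, extent,
    cellsize); extent is (lon_min, lon_max, lat_min, lat_max)."""
    header: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines[:6]):
        parts = line.split()
        if len(parts) != 2:
            raise SchemaError(f"{path}: malformed header line {i + 1}: {line!r}")
        header[parts[0].lower()] = float(parts[1])
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    if set(header) != required:
        raise SchemaError(f"{path}: header keys {sorted(header)} != {sorted(required)}")
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    values = np.loadtxt(lines[6:])
    values = values.reshape(n_rows, n_cols)
    values = np.where(values == header["nodata_value"], np.nan, values)
    res = header["cellsize"]
    extent = (
        header["xllcorner"],
        header["xllcorner"] + n_cols * res,
        header["yllcorner"],
        header["yllcorner"] + n_rows * res,
    )
    return values, extent, res


def write_env_grid(directory, env: EnvGrid) -> list[Path]:
    """Write every layer of an environment as <layer>.asc in a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, layer in env.layers.items():
        values = np.where(env.mask, layer, np.nan)
        p = directory / f"{name}.asc"
        write_ascii_grid(p, values, env.extent, env.resolution)
        paths.append(p)
    return paths


def read_env_grid(directory) -> EnvGrid:
    """Assemble an EnvGrid from all .asc files in a directory; cells that are
    NODATA in any layer are masked invalid."""
    directory = Path(directory)
    files = sorted(directory.glob("*.asc"))
    if not files:
        raise SchemaError(f"no .asc layers found in {directory}")
    layers: dict[str, np.ndarray] = {}
    meta = None
    for f in files:
        values, extent, res = read_ascii_grid(f)
        if meta is None:
            meta = (extent, res, values.shape)
        elif (extent, res, values.shape) != meta:
            raise SchemaError(f"{f}: grid geometry differs from {files[0]}")
        layers[f.stem] = values
    mask = np.all([~np.isnan(v) for v in layers.values()], axis=0)
    extent, res, _ = meta
    return EnvGrid(extent=extent, resolution=res, layers=layers, mask=mask)


def write_surface(path, surface: SuitabilitySurface) -> None:
    write_ascii_grid(path, surface.values, surface.grid.extent, surface.grid.resolution)


# -------------------------------------------------------------------- tables

def occurrences_to_frame(sets: list[OccurrenceSet]) -> pd.DataFrame:
    rows = [
        {"species": s.species, "lon": lon, "lat": lat, "role": s.role}
        for s in sets
        for lon, lat in s.points
    ]
    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)


def write_occurrences(path, sets: list[OccurrenceSet]) -> None:
    occurrences_to_frame(sets).to_csv(path, index=False)


def read_occurrences(path, species: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, OCCURRENCE_COLUMNS, f"occurrences {path}")
    bad_role = df[~df["role"].isin(["presence", "pseudo_absence"])]
    if not bad_role.empty:
        raise SchemaError(
            f"occurrences {path}: invalid role at row {bad_role.index[0] + 2}"
        )
    _check_species(df["species"], species, f"occurrences {path}")
    return df


def occurrence_sets(df: pd.DataFrame) -> list[OccurrenceSet]:
    """Group an occurrences table back into per-species, per-role point sets."""
    return [
        OccurrenceSet(species=sp, points=grp[["lon", "lat"]].to_numpy(), role=role)
        for (sp, role), grp in df.groupby(["species", "role"], sort=True)
    ]


def flowering_to_frame(records: list[FloweringRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=FLOWERING_COLUMNS)


def write_flowering(path, records: list[FloweringRecord] | pd.DataFrame) -> None:
    df = records if isinstance(records, pd.DataFrame) else flowering_to_frame(records)
    df.to_csv(path, index=False)


def read_flowering(path, season_length: int | None = None,
                   species: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, FLOWERING_COLUMNS, f"flowering {path}")
    bad = df[(df["onset_day"] < 1)]
    if season_length is not None:
        bad = pd.concat([bad, df[df["onset_day"] > season_length]])
    if not bad.empty:
        raise SchemaError(
            f"flowering {path}: onset_day out of season at row {bad.index[0] + 2}"
        )
    _check_species(df["species"], species, f"flowering {path}")
    return df


def crosses_to_frame(records: list[CrossRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records], columns=CROSS_COLUMNS)


def write_crosses(path, records: list[CrossRecord] | pd.DataFrame) -> None:
    df = records if isinstance(records, pd.DataFrame) else crosses_to_frame(records)
    df.to_csv(path, index=False)


def read_crosses(path, species: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CROSS_COLUMNS, f"crosses {path}")
    for upper, lower in (("n_pollinations", "n_fruits"), ("n_seeds_total", "n_seeds_viable")):
        bad = df[df[lower] > df[upper]]
        if not bad.empty:
            raise SchemaError(
                f"crosses {path}: {lower} exceeds {upper} at row {bad.index[0] + 2}"
            )
    _check_species(pd.concat([df["acceptor"], df["donor"]]), species, f"crosses {path}")
    return df


def _check_species(col: pd.Series, species: list[str] | None, what: str) -> None:
    if species is None:
        return
    unknown = sorted(set(col) - set(species))
    if unknown:
        raise SchemaError(f"{what}: unknown species labels {unknown}")


# ----------------------------------------------------- matrices, trees, JSON

def write_matrix(path, mat: pd.DataFrame) -> None:
    mat.to_csv(path, index_label="species")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = None
    if list(df.index) != list(df.columns):
        raise SchemaError(f"matrix {path}: row and column labels differ")
    return df


def write_newick_file(path, newick: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(newick.strip() + "\n")


def read_newick_file(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        return fh.read().strip()


def write_json(path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
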