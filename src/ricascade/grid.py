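"""Gridded environmental data and per-species suitability surfaces.

Conventions: unprojected decimal degrees, lon/lat order, row 0 is the
northernmost row, coordinates refer to cell centers, extents are half-open
(``n_cols = floor(lon_span / resolution)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EnvGrid:
    """A rectangular multi-layer environmental raster.

    ``layers`` maps layer names to (n_rows, n_cols) float arrays sharing one
    shape; ``mask`` is True where cells are valid (non-NODATA).
    """

    extent: tuple[float, float, float, float]  # lon_min, lon_max, lat_min, lat_max
    resolution: float
    layers: dict[str, np.ndarray]
    mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {l.shape for l in self.layers.values()} | {self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"layers and mask shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_rows(self) -> int:
        return self.mask.shape[0]

    @property
    def n_cols(self) -> int:
        return self.mask.shape[1]

    @property
    def lat_top(self) -> float:
        """Latitude of the grid's northern edge (lat_min + n_rows * res)."""
        return self.extent[2] + self.n_rows * self.resolution

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell (lon, lat) center coordinates, each of shape (n_rows, n_cols)."""
        lon_min = self.extent[0]
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lons = lon_min + (cols + 0.5) * self.resolution
        lats = self.lat_top - (rows + 0.5) * self.resolution
        return np.meshgrid(lons, lats)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside the grid."""
        lon_min, _, lat_min, _ = self.extent
        col = int(np.floor((lon - lon_min) / self.resolution))
        row = int(np.floor((self.lat_top - lat) / self.resolution))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) outside grid extent {self.extent}")
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        try:
            r, c = self.cell_of(lon, lat)
        except ValueError:
            return False
        return bool(self.mask[r, c])


@dataclass
class SuitabilitySurface:
    """Per-cell occurrence probability of one species on an :class:`EnvGrid`.

    Unnormalized values lie in [0, 1] (model probabilities); after
    :func:`ricascade.overlap.normalize_surface` the valid cells sum to 1 and
    the surface is a probability distribution over sites, the p_X,i entering
    Schoener's D.  Invalid cells hold NaN.
    """

    species: str
    values: np.ndarray
    grid: EnvGrid
    normalized: bool = False

    def valid_values(self) -> np.ndarray:
        """Values at valid cells, as a flat array."""
        return self.values[self.grid.mask]


@dataclass
class OccurrenceSet:
    """Presence or pseudo-absence points of one species, in decimal degrees."""

    species: str
    points: np.ndarray  # (n, 2) array of (lon, lat)
    role: str = "presence"  # presence | pseudo_absence

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.role not in ("presence", "pseudo_absence"):
            raise ValueError(f"role must be presence|pseudo_absence, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.points)
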