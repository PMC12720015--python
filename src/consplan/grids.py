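"""Planar equal-area grids and the raster-like containers shared by every stage.

All spatial data live on a regular grid in planar equal-area coordinates
(kilometres).  A cell of side ``cell_size_km`` therefore has a true area of
``cell_size_km**2`` km², so occupied-cell counts convert to areas by a single
multiplication.  Layers are dense ``(nrows, ncols)`` numpy arrays with row 0
at the top (the northernmost row), matching the ESRI ASCII grid convention
used for on-disk exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "GridSpec",
    "EnvStack",
    "BinaryRange",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    Parameters
    ----------
    nrows, ncols : int
        Grid dimensions; ``nrows * ncols >= 4``.
    cell_size_km : float
        Side length of a (square) cell in km; cell area is ``cell_size_km**2``.
    origin_xy : tuple of float
        Planar coordinates (km) of the lower-left corner of the grid.
    """

    nrows: int
    ncols: int
    cell_size_km: float = 1.0
    origin_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.nrows * self.ncols < 4:
            raise ValueError("grid must contain at least 4 cells")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid bounding box."""
        x0, y0 = self.origin_xy
        return (
            x0,
            y0,
            x0 + self.ncols * self.cell_size_km,
            y0 + self.nrows * self.cell_size_km,
        )

    def cell_of(self, x, y):
        """Map planar coordinates to (row, col) indices (vectorized).

        Row 0 is the top row; points on the exact upper/right edge clip into
        the last cell so the closed bounding box maps onto the grid.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin_xy
        col = np.floor((x - x0) / self.cell_size_km).astype(int)
        row_from_bottom = np.floor((y - y0) / self.cell_size_km).astype(int)
        col = np.clip(col, 0, self.ncols - 1)
        row_from_bottom = np.clip(row_from_bottom, 0, self.nrows - 1)
        row = self.nrows - 1 - row_from_bottom
        return row, col

    def xy_of(self, row, col):
        """Planar coordinates of cell centres (vectorized)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x0, y0 = self.origin_xy
        x = x0 + (col + 0.5) * self.cell_size_km
        y = y0 + (self.nrows - row - 0.5) * self.cell_size_km
        return x, y

    def contains(self, x, y):
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)


class EnvStack:
    """An ordered stack of environmental layers sharing one grid.

    Layers are name → ``(nrows, ncols)`` float arrays; ``scenario`` tags the
    stack as ``current``, ``future_replicate_<k>`` or ``future_mean``.
    """

    def __init__(
        self,
        grid: GridSpec,
        layers: Mapping[str, np.ndarray],
        scenario: str = "current",
    ):
        self.grid = grid
        self.layers: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != grid.shape:
                raise ValueError(
                    f"layer {name!r} has shape {arr.shape}, expected {grid.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"layer {name!r} contains non-finite values")
            self.layers[name] = arr
        self.scenario = scenario

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    def select(self, names) -> "EnvStack":
        """Sub-stack restricted to ``names`` (order preserved)."""
        return EnvStack(self.grid, {n: self.layers[n] for n in names}, self.scenario)

    def as_matrix(self, names=None) -> np.ndarray:
        """Flattened design matrix, one column per layer, one row per cell."""
        names = list(names) if names is not None else self.layer_names
        return np.column_stack([self.layers[n].ravel() for n in names])

    def copy(self, scenario: str | None = None) -> "EnvStack":
        return EnvStack(
            self.grid,
            {n: a.copy() for n, a in self.layers.items()},
            scenario or self.scenario,
        )

    def write(self, directory: str | Path) -> None:
        """Write each layer as ``<name>.asc`` (ESRI ASCII grid)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", arr, self.grid)


@dataclass
class BinaryRange:
    """A species' binary presence map under one scenario.

    ``c`` (the occupied-cell count) is the quantity the rarity score and the
    tiered conservation targets are built from.
    """

    species_id: str
    scenario: str
    grid: GridSpec
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("range mask shape does not match grid")

    @property
    def c(self) -> int:
        """Number of occupied grid cells."""
        return int(self.mask.sum())

    @property
    def area_km2(self) -> float:
        return self.c * self.grid.cell_area_km2

    @property
    def is_empty(self) -> bool:
        return self.c == 0

    def intersect(self, other: "BinaryRange", scenario: str | None = None) -> "BinaryRange":
        if other.grid != self.grid:
            raise ValueError("grid mismatch")
        return BinaryRange(
            self.species_id,
            scenario or self.scenario,
            self.grid,
            self.mask & other.mask,
        )


def write_ascii_grid(path: str | Path, array: np.ndarray, grid: GridSpec,
                     nodata: float = -9999.0) -> None:
    """Write a layer as a plain-text ESRI ASCII grid."""
    array = np.asarray(array, dtype=float)
    if array.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    x0, y0 = grid.origin_xy
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {y0}\n"
        f"cellsize {grid.cell_size_km}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, array, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; returns (array, GridSpec)."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        array = np.loadtxt(fh)
    grid = GridSpec(
        nrows=int(meta["nrows"]),
        ncols=int(meta["ncols"]),
        cell_size_km=meta["cellsize"],
        origin_xy=(meta["xllcorner"], meta["yllcorner"]),
    )
    array = array.reshape(grid.shape)
    return array, grid
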