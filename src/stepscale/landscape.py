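"""Raster data model, synthetic landscape generation, and raster/trajectory I/O.

Rasters follow the ESRI ASCII grid convention on disk (header of six
``key value`` lines followed by row-major values, top row first).  In
memory, ``RasterLayer.values[i, j]`` indexes row ``i`` counted from the
*bottom* of the grid, so that cell ``(i, j)`` covers the half-open square
``[x0 + j*cs, x0 + (j+1)*cs) x [y0 + i*cs, y0 + (i+1)*cs)`` and continuous
coordinates increase with array index in both axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RasterLayer",
    "StudyArea",
    "Trajectory",
    "generate_resource_layer",
    "read_raster",
    "write_raster",
    "read_trajectories",
    "write_trajectories",
    "bearing_between",
]


@dataclass
class RasterLayer:
    """A regular-grid field of real values (resource layer, OD or UD).

    Parameters
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Cell values; row 0 is the *bottom* row of the grid.
    cell_size : float
        Length units per cell edge.
    origin : (float, float)
        ``(x0, y0)`` of the lower-left corner of the grid.
    name : str
        Label for the layer.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("raster must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("raster values must all be finite")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of cell-centre coordinates, aligned with `values`."""
        x0, y0 = self.origin
        cs = self.cell_size
        xs = x0 + (np.arange(self.n_cols) + 0.5) * cs
        ys = y0 + (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Containing cell (i, j) of a continuous point; half-open cells."""
        x0, y0 = self.origin
        j = int(math.floor((x - x0) / self.cell_size))
        i = int(math.floor((y - y0) / self.cell_size))
        if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
            raise ValueError(f"point ({x}, {y}) lies outside the raster")
        return i, j

    def value_at(self, x: float, y: float) -> float:
        i, j = self.cell_of(x, y)
        return float(self.values[i, j])

    def same_grid(self, other: "RasterLayer") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
        )


@dataclass
class StudyArea:
    """The study region Omega: a raster geometry plus a set of admissible cells.

    By default every cell is admissible.  Movement kernels place zero mass
    outside the admissible set (the "no go" boundary condition).
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    admissible: np.ndarray | None = None  # boolean mask, shape (n_rows, n_cols)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.cell_size <= 0:
            raise ValueError("invalid study-area geometry")
        if self.admissible is None:
            self.admissible = np.ones((self.n_rows, self.n_cols), dtype=bool)
        else:
            self.admissible = np.asarray(self.admissible, dtype=bool)
            if self.admissible.shape != (self.n_rows, self.n_cols):
                raise ValueError("admissible mask shape must match the grid")

    @classmethod
    def from_raster(cls, layer: RasterLayer) -> "StudyArea":
        return cls(layer.n_rows, layer.n_cols, layer.cell_size, layer.origin)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        cs = self.cell_size
        xs = x0 + (np.arange(self.n_cols) + 0.5) * cs
        ys = y0 + (np.arange(self.n_rows) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        x0, y0 = self.origin
        j = int(math.floor((x - x0) / self.cell_size))
        i = int(math.floor((y - y0) / self.cell_size))
        if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
            raise ValueError(f"point ({x}, {y}) lies outside the study area")
        return i, j

    def contains(self, x: float, y: float) -> bool:
        x0, y0 = self.origin
        return (
            x0 <= x < x0 + self.n_cols * self.cell_size
            and y0 <= y < y0 + self.n_rows * self.cell_size
        )

    def centre_of(self, i: int, j: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (j + 0.5) * self.cell_size, y0 + (i + 0.5) * self.cell_size)

    def blank_layer(self, name: str = "") -> RasterLayer:
        return RasterLayer(
            np.zeros(self.shape), self.cell_size, self.origin, name=name
        )


def bearing_between(x1: float, y1: float, x2: float, y2: float) -> float:
    """Bearing of the displacement (x1,y1)->(x2,y2), radians clockwise from north.

    Due north (+y) is 0; due east (+x) is pi/2.
    """
    return math.atan2(x2 - x1, y2 - y1) % (2 * math.pi)


@dataclass
class Trajectory:
    """Time-ordered locations of one individual, with arrival bearings.

    ``bearings[k]`` is the bearing on which the animal arrived at fix ``k``
    (radians clockwise from north); the first fix has no arrival bearing
    and stores NaN.
    """

    individual: str
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    bearings: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        n = len(self.times)
        if not (len(self.xs) == len(self.ys) == n):
            raise ValueError("times, xs, ys must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError(
                f"times for individual {self.individual!r} must be strictly increasing"
            )
        if self.bearings is None:
            self.bearings = self.recompute_bearings()
        else:
            self.bearings = np.asarray(self.bearings, dtype=float)
            if len(self.bearings) != n:
                raise ValueError("bearings length must match times")

    def __len__(self) -> int:
        return len(self.times)

    def recompute_bearings(self) -> np.ndarray:
        b = np.full(len(self.times), np.nan)
        for k in range(1, len(self.times)):
            b[k] = bearing_between(
                self.xs[k - 1], self.ys[k - 1], self.xs[k], self.ys[k]
            )
        return b

    def points(self) -> np.ndarray:
        """(n, 2) array of fix coordinates."""
        return np.column_stack([self.xs, self.ys])


# ---------------------------------------------------------------------------
# Synthetic landscape generation


def generate_resource_layer(
    n_rows: int,
    n_cols: int,
    smoothness: float = 10.0,
    seed: int = 0,
    cell_size: float = 1.0,
    origin: tuple[float, float] = (0.0, 0.0),
    name: str = "resource",
) -> RasterLayer:
    """Generate a smooth synthetic resource layer rescaled to [0, 1].

    White noise is low-pass filtered with a Gaussian of standard deviation
    ``smoothness`` (in cells) and min-max rescaled.  The same seed and
    parameters always give a bit-identical layer.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; each must be at least 2.
    smoothness : float
        Gaussian filter scale in cells; larger values give flatter fields.
    seed : int
        Seed for the random field.
    """
    if n_rows < 2 or n_cols < 2:
        raise ValueError(
            f"grid must be at least 2x2, got {n_rows}x{n_cols}"
        )
    if smoothness <= 0:
        raise ValueError(f"smoothness must be positive, got {smoothness}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_rows, n_cols))
    smooth = ndimage.gaussian_filter(noise, sigma=smoothness, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-300:  # numerically flat field
        values = np.full((n_rows, n_cols), 0.5)
    else:
        values = (smooth - lo) / (hi - lo)
    return RasterLayer(values, cell_size, origin, name=name)


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_raster(layer: RasterLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid (top row first on disk)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {layer.n_cols}\n")
        fh.write(f"nrows {layer.n_rows}\n")
        fh.write(f"xllcorner {layer.origin[0]!r}\n")
        fh.write(f"yllcorner {layer.origin[1]!r}\n")
        fh.write(f"cellsize {layer.cell_size!r}\n")
        fh.write("NODATA_value -9999\n")
        for row in layer.values[::-1]:  # top row first
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_raster(path: str | Path, name: str | None = None) -> RasterLayer:
    """Read an ESRI ASCII grid.

    Raises ``ValueError`` naming the offending line on a malformed header
    or a ragged row.
    """
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        lines = fh.read().splitlines()
    lineno = 0
    for lineno, line in enumerate(lines[:6], start=1):
        parts = line.split()
        if len(parts) != 2 or parts[0].lower() not in _HEADER_KEYS:
            raise ValueError(
                f"{path}: malformed header at line {lineno}: {line!r}"
            )
        header[parts[0].lower()] = float(parts[1])
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: header is missing {key!r}")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    for lineno, line in enumerate(lines[6:], start=7):
        if not line.strip():
            continue
        row = [float(v) for v in line.split()]
        if len(row) != ncols:
            raise ValueError(
                f"{path}: row at line {lineno} has {len(row)} values, expected {ncols}"
            )
        rows.append(row)
    if len(rows) != nrows:
        raise ValueError(
            f"{path}: found {len(rows)} data rows, header promises {nrows}"
        )
    values = np.asarray(rows)[::-1]  # back to bottom-row-first
    return RasterLayer(
        values,
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
        name=name if name is not None else path.stem,
    )


# ---------------------------------------------------------------------------
# Trajectory I/O (CSV: id,t,x,y[,bearing])


def write_trajectories(trajs: Iterable[Trajectory], path: str | Path) -> None:
    frames = []
    for tr in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "id": tr.individual,
                    "t": tr.times,
                    "x": tr.xs,
                    "y": tr.ys,
                    "bearing": tr.bearings,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    """Read trajectories from CSV; bearings are recomputed when absent.

    Duplicate (id, t) pairs are rejected; fixes are sorted by time per
    individual.
    """
    df = pd.read_csv(path)
    required = {"id", "t", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(subset=["id", "t"]).any():
        dup = df[df.duplicated(subset=["id", "t"])].iloc[0]
        raise ValueError(
            f"{path}: duplicate fix for id={dup['id']!r} at t={dup['t']}"
        )
    out = []
    for ind, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("t")
        bearings = (
            grp["bearing"].to_numpy() if "bearing" in grp.columns else None
        )
        out.append(
            Trajectory(
                individual=str(ind),
                times=grp["t"].to_numpy(),
                xs=grp["x"].to_numpy(),
                ys=grp["y"].to_numpy(),
                bearings=bearings,
            )
        )
    return out
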