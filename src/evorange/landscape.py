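"""Gridded landscapes, climate forcing and seed dispersal.

A landscape is a rectangular grid of square cells (default 32 × 32 cells
of 250 m). Three environmental variables define the selective optimum of
a cell: mean annual temperature and annual precipitation (time-varying,
given as decadal anchor layers 2010–2090 by a climate scenario) and the
percentage of carbonate bedrock (static). Between anchor decades the
optimum is interpolated linearly in time; before 2010 it is held at the
2010 values and after 2090 at the 2090 values (climate constant after
2090).

Traits live on standardized (z-score) scales computed over the initial
landscape so selection variances anchored to niche widths are comparable
across variables; raw units are kept for raster I/O.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genetics import N_TRAITS

__all__ = [
    "VARIABLES",
    "Landscape",
    "ClimateScenario",
    "EnvScaler",
    "theta_at",
    "theta_field",
    "disperse_seeds",
    "grid_area",
    "read_ascii_grid",
    "write_ascii_grid",
]

#: trait/environmental-variable order used throughout
VARIABLES = ("temperature", "precipitation", "carbonate")

ANCHOR_YEARS = np.arange(2010, 2091, 10)
YEAR_MIN, YEAR_MAX = 2000, 2150


@dataclass
class Landscape:
    """Static landscape layers plus grid geometry."""

    carbonate: np.ndarray        # (R, C), static
    temperature: np.ndarray      # (R, C), baseline (2010) layer
    precipitation: np.ndarray    # (R, C), baseline (2010) layer
    cell_size: float = 250.0     # metres

    def __post_init__(self) -> None:
        self.carbonate = np.asarray(self.carbonate, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.precipitation = np.asarray(self.precipitation, dtype=float)
        if not (self.carbonate.shape == self.temperature.shape
                == self.precipitation.shape):
            raise ValueError("all landscape layers must share one grid shape")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.carbonate.shape

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))


@dataclass
class ClimateScenario:
    """Decadal climate anchors 2010–2090 for the two climatic variables.

    ``temperature`` and ``precipitation`` have shape ``(9, R, C)`` — one
    layer per anchor year 2010, 2020, …, 2090. Climate is constant after
    2090.
    """

    name: str
    temperature: np.ndarray
    precipitation: np.ndarray
    anchor_years: np.ndarray = field(default_factory=lambda: ANCHOR_YEARS.copy())

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.precipitation = np.asarray(self.precipitation, dtype=float)
        n = len(self.anchor_years)
        if self.temperature.shape[0] != n or self.precipitation.shape[0] != n:
            raise ValueError("need one climate layer per anchor year")

    @classmethod
    def constant(cls, landscape: Landscape, name: str = "constant") -> "ClimateScenario":
        n = len(ANCHOR_YEARS)
        return cls(
            name,
            np.broadcast_to(landscape.temperature, (n,) + landscape.shape).copy(),
            np.broadcast_to(landscape.precipitation, (n,) + landscape.shape).copy(),
        )


def _interp_layer(layers: np.ndarray, anchor_years: np.ndarray,
                  year: float) -> np.ndarray:
    y = float(np.clip(year, anchor_years[0], anchor_years[-1]))
    if y <= anchor_years[0]:
        return layers[0]
    if y >= anchor_years[-1]:
        return layers[-1]
    j = int(np.searchsorted(anchor_years, y, side="right"))
    y0, y1 = anchor_years[j - 1], anchor_years[j]
    w = (y - y0) / (y1 - y0)
    return (1 - w) * layers[j - 1] + w * layers[j]


def theta_field(landscape: Landscape, scenario: ClimateScenario,
                year: float) -> np.ndarray:
    """Per-cell optimum vectors at ``year``; shape ``(R, C, 3)``.

    Annual values are linearly interpolated between decadal anchors,
    clamped to the 2010 layers before 2010 and the 2090 layers after
    2090. Years outside [2000, 2150] are rejected.
    """
    if not YEAR_MIN <= year <= YEAR_MAX:
        raise ValueError(f"year must lie in [{YEAR_MIN}, {YEAR_MAX}]")
    t = _interp_layer(scenario.temperature, scenario.anchor_years, year)
    p = _interp_layer(scenario.precipitation, scenario.anchor_years, year)
    return np.stack([t, p, landscape.carbonate], axis=-1)


def theta_at(landscape: Landscape, scenario: ClimateScenario,
             cell: tuple[int, int], year: float) -> np.ndarray:
    """Optimum (temperature, precipitation, carbonate) of one cell."""
    return theta_field(landscape, scenario, year)[cell[0], cell[1]]


@dataclass
class EnvScaler:
    """Z-score transform of the three environmental variables.

    Fitted on the initial (2010) landscape so trait values, selection
    variances and niche widths share a common, comparable scale.
    """

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, landscape: Landscape, scenario: ClimateScenario) -> "EnvScaler":
        field0 = theta_field(landscape, scenario, 2010.0).reshape(-1, N_TRAITS)
        sd = field0.std(axis=0, ddof=0)
        if np.any(sd == 0):
            sd = np.where(sd == 0, 1.0, sd)  # constant layer: leave it unscaled
        return cls(field0.mean(axis=0), sd)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values, dtype=float) * self.sd + self.mean


def grid_area(landscape: Landscape) -> float:
    """Total grid area in km² (rows · cols · cell_size²)."""
    r, c = landscape.shape
    return r * c * (landscape.cell_size / 1000.0) ** 2


def disperse_seeds(origin_rows: np.ndarray, origin_cols: np.ndarray,
                   grid_shape: tuple[int, int], cell_size: float,
                   m: float, mean_distance_m: float,
                   rng: np.random.Generator,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dispersal of seeds between cells.

    Each seed stays in its natal cell with probability ``1 − m``;
    otherwise it moves a distance drawn from a negative-exponential
    kernel with mean ``mean_distance_m`` in a uniform direction. Seeds
    landing outside the grid are lost (absorbing boundary).

    Returns ``(rows, cols, lost)`` where ``lost`` marks off-grid seeds
    (their row/col entries are not meaningful).
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("dispersal probability m must lie in [0, 1]")
    if mean_distance_m < 0 or cell_size <= 0:
        raise ValueError("invalid kernel parameters")
    n = origin_rows.shape[0]
    rows = np.asarray(origin_rows, dtype=np.int64).copy()
    cols = np.asarray(origin_cols, dtype=np.int64).copy()
    if n == 0 or m == 0.0:
        return rows, cols, np.zeros(n, dtype=bool)
    move = rng.random(n) < m
    k = int(move.sum())
    if k:
        dist = rng.exponential(mean_distance_m, size=k)
        angle = rng.uniform(0.0, 2.0 * np.pi, size=k)
        drow = np.rint(dist * np.sin(angle) / cell_size).astype(np.int64)
        dcol = np.rint(dist * np.cos(angle) / cell_size).astype(np.int64)
        rows[move] += drow
        cols[move] += dcol
    R, C = grid_shape
    lost = (rows < 0) | (rows >= R) | (cols < 0) | (cols >= C)
    return rows, cols, lost


# ---------------------------------------------------------------------------
# plain-text raster I/O (ESRI ASCII grid dialect)

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "NODATA_value")


def write_ascii_grid(path: str | Path, grid: np.ndarray, cellsize: float,
                     xllcorner: float = 0.0, yllcorner: float = 0.0,
                     nodata: float = -9999.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid (row 0 = northernmost)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("raster must be 2-D")
    buf = io.StringIO()
    buf.write(f"ncols {grid.shape[1]}\n")
    buf.write(f"nrows {grid.shape[0]}\n")
    buf.write(f"xllcorner {xllcorner:.6f}\n")
    buf.write(f"yllcorner {yllcorner:.6f}\n")
    buf.write(f"cellsize {cellsize:.6f}\n")
    buf.write(f"NODATA_value {nodata:.6f}\n")
    np.savetxt(buf, grid, fmt="%.10g")
    Path(path).write_text(buf.getvalue())


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict[str, float]]:
    """Read an ESRI ASCII grid; returns ``(array, header)``."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0] in _HEADER_KEYS:
            header[parts[0]] = float(parts[1])
        else:
            break
    if not {"ncols", "nrows", "cellsize"} <= set(header):
        raise ValueError(f"{path}: not an ASCII grid (incomplete header)")
    data = np.loadtxt(io.StringIO("\n".join(lines[i:])))
    data = np.atleast_2d(data)
    expect = (int(header["nrows"]), int(header["ncols"]))
    if data.shape != expect:
        raise ValueError(f"{path}: data shape {data.shape} != header {expect}")
    return data, header
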