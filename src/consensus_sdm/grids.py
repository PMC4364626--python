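"""Gridded environmental data containers.

The study unit is a rectangular raster of square cells. An :class:`EnvGrid`
stacks named environmental layers (climate, soil, elevation) over one shared
validity mask; a :class:`SpeciesDistribution` is a binary presence grid aligned
to it; a :class:`ScenarioSet` holds future-climate variants of the baseline
grid indexed by (GCM, emissions scenario, period).

No map projection is modelled: cell centres get geographic coordinates from
the grid origin, the cell size in km, and a local equirectangular
approximation (111.32 km per degree latitude; longitude scaled by the cosine
of the grid's mean latitude). North is up: latitude decreases with row index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

KM_PER_DEG_LAT = 111.32

#: the five thermal variables every grid must carry (deg C or degree-days)
THERMAL_LAYERS = ("MAT", "MWMT", "MCMT", "TD", "DD")

PERIODS = ("2020s", "2050s", "2080s")


class GridAlignmentError(ValueError):
    """Raised when two grids that must share geometry do not."""


@dataclass
class EnvGrid:
    """Aligned stack of named environmental raster layers.

    Parameters
    ----------
    layer_names : list of str
        Variable identifiers, e.g. ``MAT``, ``MAP``, ``ELEV``.
    values : ndarray, shape (n_layers, rows, cols)
        Layer values; must be finite on masked-in cells.
    mask : ndarray of bool, shape (rows, cols)
        True marks valid (land) cells.
    cell_size_km : float
        Edge length of one square cell, km.
    origin_latlon : (float, float)
        Latitude/longitude of the centre of cell (0, 0), i.e. the
        north-west corner cell.
    """

    layer_names: list[str]
    values: np.ndarray
    mask: np.ndarray
    cell_size_km: float = 8.0
    origin_latlon: tuple[float, float] = (50.0, 100.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_layers, rows, cols)")
        if len(self.layer_names) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.layer_names)} layer names for "
                f"{self.values.shape[0]} layers"
            )
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("duplicate layer names")
        if self.mask.shape != self.values.shape[1:]:
            raise ValueError("mask shape does not match layer shape")
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if not np.all(np.isfinite(self.values[:, self.mask])):
            raise ValueError("non-finite values on masked-in cells")

    # -- geometry ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_cells(self) -> int:
        """Number of masked-in cells."""
        return int(self.mask.sum())

    def latitudes(self) -> np.ndarray:
        """Latitude of each row's cell centres (decreasing: north is up)."""
        rows = np.arange(self.shape[0])
        return self.origin_latlon[0] - rows * self.cell_size_km / KM_PER_DEG_LAT

    def longitudes(self) -> np.ndarray:
        """Longitude of each column's cell centres."""
        cols = np.arange(self.shape[1])
        mean_lat = float(np.mean(self.latitudes()))
        km_per_deg_lon = KM_PER_DEG_LAT * math.cos(math.radians(mean_lat))
        return self.origin_latlon[1] + cols * self.cell_size_km / km_per_deg_lon

    def cell_latlon(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) arrays of shape (rows, cols) for every cell centre."""
        lat = np.broadcast_to(self.latitudes()[:, None], self.shape)
        lon = np.broadcast_to(self.longitudes()[None, :], self.shape)
        return lat, lon

    # -- access ------------------------------------------------------------

    def layer(self, name: str) -> np.ndarray:
        try:
            i = self.layer_names.index(name)
        except ValueError:
            raise KeyError(f"no layer named {name!r}; have {self.layer_names}")
        return self.values[i]

    def has_layers(self, names: Iterable[str]) -> bool:
        return set(names) <= set(self.layer_names)

    def table(self, layers: Iterable[str] | None = None) -> pd.DataFrame:
        """Masked-in cells as rows; one column per layer plus row/col/cell_id.

        cell_id is the row-major flat index, stable across aligned grids.
        """
        layers = list(layers) if layers is not None else list(self.layer_names)
        rows, cols = np.nonzero(self.mask)
        out = pd.DataFrame(
            {
                "cell_id": rows * self.shape[1] + cols,
                "row": rows,
                "col": cols,
            }
        )
        for name in layers:
            out[name] = self.layer(name)[rows, cols]
        return out

    def with_values(self, values: np.ndarray,
                    layer_names: list[str] | None = None) -> "EnvGrid":
        """New grid sharing this grid's geometry with replaced layer values."""
        return EnvGrid(
            layer_names=list(layer_names or self.layer_names),
            values=values,
            mask=self.mask.copy(),
            cell_size_km=self.cell_size_km,
            origin_latlon=self.origin_latlon,
        )

    def check_aligned(self, other: "EnvGrid") -> None:
        if (
            self.shape != other.shape
            or not np.array_equal(self.mask, other.mask)
            or self.cell_size_km != other.cell_size_km
            or self.origin_latlon != other.origin_latlon
        ):
            raise GridAlignmentError("grids are not aligned")


@dataclass
class SpeciesDistribution:
    """Binary presence grid aligned to an :class:`EnvGrid`."""

    presence: np.ndarray
    env: EnvGrid

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != self.env.shape:
            raise GridAlignmentError("presence grid does not match EnvGrid")
        if np.any(self.presence & ~self.env.mask):
            raise ValueError("presence on masked-out cells")
        n_pres = int(self.presence.sum())
        if n_pres == 0:
            raise ValueError("species has no presence cells")
        if n_pres == self.env.n_cells:
            raise ValueError("species present everywhere: no absences")

    @property
    def n_presences(self) -> int:
        return int(self.presence.sum())

    @property
    def prevalence(self) -> float:
        """Fraction of masked-in cells occupied."""
        return self.n_presences / self.env.n_cells


@dataclass
class ScenarioSet:
    """Baseline grid plus one perturbed grid per (gcm, sres, period)."""

    baseline: EnvGrid
    scenario_grids: dict[tuple[int, int, str], EnvGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, grid in self.scenario_grids.items():
            gcm, sres, period = key
            if period not in PERIODS:
                raise ValueError(f"unknown period {period!r}")
            if gcm not in (1, 2, 3) or sres not in (1, 2, 3):
                raise ValueError(f"gcm/sres ids must be in 1..3, got {key}")
            self.baseline.check_aligned(grid)

    @property
    def periods(self) -> list[str]:
        return sorted({p for (_, _, p) in self.scenario_grids},
                      key=PERIODS.index)

    def for_period(self, period: str) -> dict[tuple[int, int], EnvGrid]:
        out = {
            (g, s): grid
            for (g, s, p), grid in self.scenario_grids.items()
            if p == period
        }
        if len(out) != 9:
            raise ValueError(
                f"period {period!r} has {len(out)} scenario grids, expected 9"
            )
        return out


# -- plain-text raster I/O -------------------------------------------------
#
# ESRI ASCII grid: 6 header lines then rows of numbers, row 0 = north.
# NODATA cells encode the mask.

_NODATA = -9999.0


def write_ascii_grid(path: str | Path, array: np.ndarray, mask: np.ndarray,
                     cell_size_km: float, origin_latlon: tuple[float, float]) -> None:
    array = np.where(mask, array, _NODATA)
    rows, cols = array.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {origin_latlon[1]:.6f}\n"
        f"yllcorner {origin_latlon[0]:.6f}\n"
        f"cellsize {cell_size_km:.6f}\n"
        f"NODATA_value {_NODATA:.1f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, array, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, float, tuple[float, float]]:
    """Returns (values, mask, cell_size_km, origin_latlon)."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        array = np.loadtxt(fh)
    array = array.reshape(int(header["nrows"]), int(header["ncols"]))
    mask = array != header["nodata_value"]
    values = np.where(mask, array, np.nan)
    return values, mask, header["cellsize"], (header["yllcorner"], header["xllcorner"])


def save_env_grid(env: EnvGrid, directory: str | Path) -> None:
    """One .asc file per layer under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in env.layer_names:
        write_ascii_grid(directory / f"{name}.asc", env.layer(name),
                         env.mask, env.cell_size_km, env.origin_latlon)


def load_env_grid(directory: str | Path, layer_names: list[str]) -> EnvGrid:
    directory = Path(directory)
    layers, mask = [], None
    cell_size, origin = None, None
    for name in layer_names:
        values, m, cell_size, origin = read_ascii_grid(directory / f"{name}.asc")
        layers.append(np.where(m, values, 0.0))
        mask = m if mask is None else mask & m
    return EnvGrid(layer_names=list(layer_names), values=np.stack(layers),
                   mask=mask, cell_size_km=cell_size, origin_latlon=origin)


def save_species(species: SpeciesDistribution, path: str | Path) -> None:
    """Presence grid as a 0/1 CSV matrix (off-mask cells written as 0)."""
    np.savetxt(path, species.presence.astype(int), fmt="%d", delimiter=",")


def load_species(path: str | Path, env: EnvGrid) -> SpeciesDistribution:
    presence = np.loadtxt(path, delimiter=",").astype(bool)
    return SpeciesDistribution(presence=presence, env=env)
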