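"""Gridded environmental layers on a shared geographic (WGS84) grid.

An :class:`EnvStack` holds named 2-D layers that are co-registered on one
regular lon/lat grid. Row 0 is the northern edge; coordinates are
cell-center registered. Stacks are serialized as one ESRI ASCII grid
(``.asc``) per layer plus a JSON manifest, so every artifact is plain text.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "EnvStack",
    "cell_area_km2",
    "haversine_km",
    "read_stack",
]


@dataclass
class EnvStack:
    """Named, co-registered raster layers on one geographic grid.

    Parameters
    ----------
    layers
        Mapping from variable name to a 2-D float array. All layers must
        share one shape. ``nodata`` cells carry the sentinel value.
    x_origin, y_origin
        Longitude of the western edge and latitude of the northern edge of
        the grid, in degrees.
    cell_size
        Square cell size in degrees.
    nodata
        Sentinel for missing cells.
    scenario
        Free-form scenario tag (e.g. ``"near-current"``, ``"2050s_ssp5-8.5"``).
    """

    layers: dict[str, np.ndarray]
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 1.0
    nodata: float = -9999.0
    scenario: str = "near-current"
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers have mismatched shapes: {sorted(shapes)}")
        self.layers = {k: np.asarray(v, dtype=float) for k, v in self.layers.items()}

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.layers.values()))
        return first.shape

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def same_grid(self, other: "EnvStack") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.x_origin, other.x_origin)
            and math.isclose(self.y_origin, other.y_origin)
            and math.isclose(self.cell_size, other.cell_size)
        )

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def point_to_rowcol(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(lon) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(lat)) / self.cell_size).astype(int)
        return row, col

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        row, col = self.point_to_rowcol(lon, lat)
        nrow, ncol = self.shape
        return (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)

    def valid_mask(self) -> np.ndarray:
        """Cells where every layer is finite and not nodata."""
        mask = np.ones(self.shape, dtype=bool)
        for arr in self.layers.values():
            mask &= np.isfinite(arr) & (arr != self.nodata)
        return mask

    def cell_areas_km2(self) -> np.ndarray:
        """Spherical area of every cell, km^2, broadcast over the grid."""
        nrow, ncol = self.shape
        rows = np.arange(nrow)
        lat_top = self.y_origin - rows * self.cell_size
        lat_bot = lat_top - self.cell_size
        col_areas = cell_area_km2(lat_bot, lat_top, self.cell_size)
        return np.repeat(col_areas[:, None], ncol, axis=1)

    def to_matrix(self, names: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Flatten valid cells into an (n_valid, n_layers) matrix.

        Returns the matrix and the flat indices of the valid cells.
        """
        names = names or self.names
        mask = self.valid_mask()
        idx = np.flatnonzero(mask.ravel())
        mat = np.column_stack([self.layers[n].ravel()[idx] for n in names])
        return mat, idx

    # -- I/O ----------------------------------------------------------------

    def write(self, directory: str | Path) -> Path:
        """Write one ``.asc`` per layer plus ``stack.json``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nrow, ncol = self.shape
        header = (
            f"ncols {ncol}\nnrows {nrow}\n"
            f"xllcorner {self.x_origin}\nyllcorner {self.y_origin - nrow * self.cell_size}\n"
            f"cellsize {self.cell_size}\nNODATA_value {self.nodata}\n"
        )
        for name, arr in self.layers.items():
            out = np.where(np.isfinite(arr), arr, self.nodata)
            with open(directory / f"{name}.asc", "w") as fh:
                fh.write(header)
                np.savetxt(fh, out, fmt="%.10g")
        manifest = {
            "layers": self.names,
            "x_origin": self.x_origin,
            "y_origin": self.y_origin,
            "cell_size": self.cell_size,
            "nodata": self.nodata,
            "scenario": self.scenario,
            "crs": self.crs,
        }
        (directory / "stack.json").write_text(json.dumps(manifest, indent=2))
        return directory


def read_stack(directory: str | Path) -> EnvStack:
    """Read a stack written by :meth:`EnvStack.write`."""
    directory = Path(directory)
    manifest = json.loads((directory / "stack.json").read_text())
    layers: dict[str, np.ndarray] = {}
    for name in manifest["layers"]:
        with open(directory / f"{name}.asc") as fh:
            for _ in range(6):
                fh.readline()
            layers[name] = np.loadtxt(fh, ndmin=2)
    return EnvStack(
        layers=layers,
        x_origin=manifest["x_origin"],
        y_origin=manifest["y_origin"],
        cell_size=manifest["cell_size"],
        nodata=manifest["nodata"],
        scenario=manifest["scenario"],
        crs=manifest.get("crs", "EPSG:4326"),
    )


def cell_area_km2(lat_bottom, lat_top, width_deg: float):
    """Spherical area of a lon/lat cell: R^2 * dlambda * (sin(top) - sin(bottom))."""
    lat_bottom = np.asarray(lat_bottom, dtype=float)
    lat_top = np.asarray(lat_top, dtype=float)
    dlam = np.deg2rad(width_deg)
    return (
        EARTH_RADIUS_KM**2
        * dlam
        * (np.sin(np.deg2rad(lat_top)) - np.sin(np.deg2rad(lat_bottom)))
    )


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))
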