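"""Minimal planar raster container with TIFF round-trip.

Rasters live in a local metric CRS (meters).  Row index increases northward,
column index eastward; the cell (row, col) has its center at
``(x0 + (col + 0.5) * cell, y0 + (row + 0.5) * cell)``.  A small
equirectangular :class:`LocalGrid` maps planar coordinates to lon/lat for
CSV round-trips; at the ~100 km scale of a desert study area the distance
error of this projection is far below GPS noise.

Files are single-band TIFFs; the geotransform and the optional lon/lat
anchor are stored as JSON in the TIFF ImageDescription tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class LocalGrid:
    """Equirectangular projection anchored at (lon0, lat0)."""

    lon0: float
    lat0: float

    def lonlat_to_xy(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        kx = EARTH_RADIUS_M * np.cos(np.radians(self.lat0))
        x = np.radians(lon - self.lon0) * kx
        y = np.radians(lat - self.lat0) * EARTH_RADIUS_M
        return x, y

    def xy_to_lonlat(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        kx = EARTH_RADIUS_M * np.cos(np.radians(self.lat0))
        lon = self.lon0 + np.degrees(x / kx)
        lat = self.lat0 + np.degrees(y / EARTH_RADIUS_M)
        return lon, lat


@dataclass
class Raster:
    values: np.ndarray          # 2-D, (nrow, ncol)
    x0: float = 0.0             # west edge (outer corner), m
    y0: float = 0.0             # south edge, m
    cell: float = 30.0          # square cell size, m
    grid: LocalGrid | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def xmax(self) -> float:
        return self.x0 + self.shape[1] * self.cell

    @property
    def ymax(self) -> float:
        return self.y0 + self.shape[0] * self.cell

    def contains(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x0) & (x <= self.xmax) & (y >= self.y0) & (y <= self.ymax)

    # -- sampling ----------------------------------------------------------
    def sample(self, x, y, method: str = "bilinear"):
        """Sample values at planar points; NaN outside the extent."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        inside = self.contains(x, y)
        nrow, ncol = self.shape
        fc = (x - self.x0) / self.cell - 0.5
        fr = (y - self.y0) / self.cell - 0.5
        out = np.full(x.shape, np.nan, dtype=float)
        if method == "nearest":
            c = np.clip(np.rint(fc).astype(int), 0, ncol - 1)
            r = np.clip(np.rint(fr).astype(int), 0, nrow - 1)
            vals = self.values[r, c].astype(float)
            out[inside] = vals[inside]
            return out, inside
        if method != "bilinear":
            raise ValueError(f"unknown sampling method {method!r}")
        # clamp to the center lattice so border half-cells extrapolate flat
        fc = np.clip(fc, 0, ncol - 1)
        fr = np.clip(fr, 0, nrow - 1)
        c0 = np.clip(np.floor(fc).astype(int), 0, ncol - 2) if ncol > 1 else np.zeros_like(fc, dtype=int)
        r0 = np.clip(np.floor(fr).astype(int), 0, nrow - 2) if nrow > 1 else np.zeros_like(fr, dtype=int)
        tc = fc - c0
        tr = fr - r0
        v = self.values.astype(float)
        c1 = np.minimum(c0 + 1, ncol - 1)
        r1 = np.minimum(r0 + 1, nrow - 1)
        val = ((1 - tr) * (1 - tc) * v[r0, c0]
               + (1 - tr) * tc * v[r0, c1]
               + tr * (1 - tc) * v[r1, c0]
               + tr * tc * v[r1, c1])
        out[inside] = val[inside]
        return out, inside

    # -- I/O ---------------------------------------------------------------
    def write_tif(self, path: str | Path) -> None:
        meta = {"x0": self.x0, "y0": self.y0, "cell": self.cell}
        if self.grid is not None:
            meta["lon0"] = self.grid.lon0
            meta["lat0"] = self.grid.lat0
        tifffile.imwrite(str(path), self.values, description=json.dumps(meta))

    @classmethod
    def read_tif(cls, path: str | Path) -> "Raster":
        with tifffile.TiffFile(str(path)) as tf:
            page = tf.pages[0]
            values = page.asarray()
            desc = page.tags.get("ImageDescription")
            meta = {}
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                except (TypeError, json.JSONDecodeError):
                    meta = {}
        grid = None
        if "lon0" in meta:
            grid = LocalGrid(lon0=float(meta["lon0"]), lat0=float(meta["lat0"]))
        return cls(values=values,
                   x0=float(meta.get("x0", 0.0)),
                   y0=float(meta.get("y0", 0.0)),
                   cell=float(meta.get("cell", 30.0)),
                   grid=grid)
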