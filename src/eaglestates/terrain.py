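"""Topographic covariates from a DEM and covariate screening.

Derives the layers used as habitat predictors: slope and aspect by Horn's
3x3 method, aspect decomposed into eastness/northness unit vectors,
topographic position index (TPI, elevation minus circular-neighborhood
mean) with a four-landform classification (canyon / steep slope / gentle
slope / ridge), and Riley's terrain ruggedness index (TRI).  Also attaches
covariates to points and applies a pairwise-correlation screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import Raster

TPI_CLASSES = {1: "canyon", 2: "steep slope", 3: "gentle slope", 4: "ridge"}
COVER_CLASSES = {1: "semidesert", 2: "forest", 3: "rock vegetation", 4: "shrubland-grassland"}

# default screening preference: most interpretable variables first; slope
# is preferred over TRI (a derived variable with the same information)
DEFAULT_KEEP_PREFERENCE = ["elevation", "slope", "northness", "eastness", "tpi", "tri"]


def derive_terrain(dem: Raster, tpi_radius_cells: int = 10) -> dict[str, Raster]:
    """Compute slope, aspect, eastness/northness, TPI, and TRI rasters.

    Returns a dict of rasters on the DEM's grid.  The one-cell border is
    masked (NaN) for the 3x3 operators; the TPI neighborhood is evaluated
    with edge replication.  Aspect is degrees clockwise from north and NaN
    where the surface is flat.
    """
    z = dem.values.astype(float)
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3 for terrain derivation")
    cell = dem.cell

    pad = np.pad(z, 1, mode="edge")
    # 3x3 neighbors, named by compass position with +row = north
    sw, s, se = pad[:-2, :-2], pad[:-2, 1:-1], pad[:-2, 2:]
    w, e = pad[1:-1, :-2], pad[1:-1, 2:]
    nw, n, ne = pad[2:, :-2], pad[2:, 1:-1], pad[2:, 2:]

    dzdx = ((ne + 2 * e + se) - (nw + 2 * w + sw)) / (8 * cell)
    dzdy = ((nw + 2 * n + ne) - (sw + 2 * s + se)) / (8 * cell)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    # aspect = azimuth of the downhill direction, clockwise from north
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    flat = (dzdx == 0) & (dzdy == 0)
    aspect[flat] = np.nan

    # Riley TRI: root of summed squared differences from the 8 neighbors
    tri = np.sqrt((sw - z) ** 2 + (s - z) ** 2 + (se - z) ** 2
                  + (w - z) ** 2 + (e - z) ** 2
                  + (nw - z) ** 2 + (n - z) ** 2 + (ne - z) ** 2)

    border = np.zeros_like(z, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for arr in (slope, aspect, tri):
        arr[border] = np.nan

    # TPI: cell elevation minus mean in a circular neighborhood
    r = int(tpi_radius_cells)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (xx ** 2 + yy ** 2) <= r ** 2
    kernel = disk / disk.sum()
    neigh_mean = ndimage.correlate(z, kernel, mode="nearest")
    tpi = z - neigh_mean

    eastness, northness = aspect_to_vectors(aspect)

    def _r(v):
        return Raster(v, x0=dem.x0, y0=dem.y0, cell=dem.cell, grid=dem.grid)

    return {
        "elevation": _r(z.copy()),
        "slope": _r(slope),
        "aspect": _r(aspect),
        "eastness": _r(eastness),
        "northness": _r(northness),
        "tpi": _r(tpi),
        "tri": _r(tri),
    }


def aspect_to_vectors(aspect_deg):
    """Decompose circular aspect into (eastness, northness) unit vectors.

    Flat cells (NaN aspect) map to (0, 0) so models stay full-rank.
    """
    a = np.asarray(aspect_deg, dtype=float)
    rad = np.radians(a)
    eastness = np.sin(rad)
    northness = np.cos(rad)
    nanmask = np.isnan(a)
    # preserve the mask on masked border cells, zero only genuinely flat ones
    eastness = np.where(nanmask, 0.0, eastness)
    northness = np.where(nanmask, 0.0, northness)
    return eastness, northness


def classify_tpi(tpi: Raster, slope: Raster, sd_cut: float = 1.0,
                 slope_break_deg: float = 6.0) -> Raster:
    """Classify standardized TPI into four landforms.

    z = tpi / sd(tpi); canyon where z <= -sd_cut, ridge where z >= +sd_cut,
    otherwise steep slope if slope >= slope_break_deg else gentle slope.
    """
    t = tpi.values.astype(float)
    s = slope.values.astype(float)
    sd = np.nanstd(t)
    out = np.full(t.shape, 3, dtype=np.uint8)  # gentle slope default
    if sd == 0 or not np.isfinite(sd):
        warnings.warn("TPI is constant (flat terrain); all cells classed gentle slope")
        return Raster(out, x0=tpi.x0, y0=tpi.y0, cell=tpi.cell, grid=tpi.grid)
    z = t / sd
    with np.errstate(invalid="ignore"):
        steep = s >= slope_break_deg
    out[steep & (np.abs(z) < sd_cut)] = 2
    out[z <= -sd_cut] = 1
    out[z >= sd_cut] = 4
    return Raster(out, x0=tpi.x0, y0=tpi.y0, cell=tpi.cell, grid=tpi.grid)


def annotate(points: pd.DataFrame, covariates: dict[str, Raster],
             landcover: Raster | None = None,
             tpi_class: Raster | None = None) -> pd.DataFrame:
    """Attach covariate values to points with x/y columns.

    Continuous layers are sampled bilinearly, categorical layers by nearest
    cell.  Points outside the raster extent get null covariates and
    ``in_extent=False``.
    """
    out = points.copy()
    x = out["x"].to_numpy(dtype=float)
    y = out["y"].to_numpy(dtype=float)
    inside_all = np.ones(len(out), dtype=bool)
    for name, ras in covariates.items():
        if name == "aspect":
            continue
        vals, inside = ras.sample(x, y, method="bilinear")
        out[name] = vals
        inside_all &= inside
    if tpi_class is not None:
        vals, inside = tpi_class.sample(x, y, method="nearest")
        out["tpi_class"] = pd.array(vals, dtype="Int64")
        out.loc[~inside, "tpi_class"] = pd.NA
        inside_all &= inside
    if landcover is not None:
        vals, inside = landcover.sample(x, y, method="nearest")
        out["landcover"] = pd.array(vals, dtype="Int64")
        out.loc[~inside, "landcover"] = pd.NA
        inside_all &= inside
    out["in_extent"] = inside_all
    cont_cols = [c for c in covariates if c != "aspect"]
    out.loc[~inside_all, cont_cols] = np.nan
    return out


@dataclass
class CollinearityReport:
    retained: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)  # (dropped, kept, r)
    constant: list[str] = field(default_factory=list)
    correlation: pd.DataFrame | None = None


def screen_collinearity(table: pd.DataFrame, threshold: float = 0.55,
                        keep_preference: list[str] | None = None) -> CollinearityReport:
    """Drop one member of every covariate pair with |Pearson r| > threshold.

    For an offending pair the variable ranked lower in ``keep_preference``
    is dropped (unlisted variables rank below listed ones).  The rule is a
    strict inequality: |r| exactly at the threshold is retained.
    """
    pref = keep_preference if keep_preference is not None else DEFAULT_KEEP_PREFERENCE
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two continuous covariates to screen")
    constant = [c for c in cols if np.nanstd(table[c].to_numpy(dtype=float)) == 0]
    active = [c for c in cols if c not in constant]
    corr = table[active].corr(method="pearson")

    def rank(name: str) -> int:
        return pref.index(name) if name in pref else len(pref) + cols.index(name)

    dropped: list[tuple[str, str, float]] = []
    changed = True
    while changed:
        changed = False
        sub = corr.loc[active, active]
        worst = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                r = sub.loc[a, b]
                # strict inequality with a float guard: |r| exactly at the
                # threshold is retained
                if np.isfinite(r) and abs(r) > threshold + 1e-9:
                    if worst is None or abs(r) > abs(worst[2]):
                        worst = (a, b, r)
        if worst is not None:
            a, b, r = worst
            loser, keeper = (a, b) if rank(a) > rank(b) else (b, a)
            active.remove(loser)
            dropped.append((loser, keeper, float(r)))
            changed = True
    return CollinearityReport(retained=active, dropped=dropped,
                              constant=constant, correlation=corr)
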