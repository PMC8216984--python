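"""Fix-quality, temporal, daylight, independence and AGL filters, and
per-step movement metrics.

The filter chain runs in a fixed order — quality -> interval subsampling ->
daylight -> natal-nest independence -> altitude above ground (AGL) — and a
ledger of removed counts is kept so that input minus output is fully
accounted for.  The daylight filter keeps fixes between civil dawn and civil
dusk (solar elevation >= -6 degrees) using the standard NOAA ephemeris
approximation.  Steps derive speed (km/h), signed and absolute turning
angle (degrees), and persistence velocity Vp = V * cos(turn) on planar
displacements, with tracks split into bursts wherever the gap exceeds twice
the nominal fix interval.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster
from .synthetic import FIX_COLUMNS

logger = logging.getLogger(__name__)

CIVIL_TWILIGHT_DEG = -6.0
SUBSAMPLE_TARGET_MIN = 15.0
SUBSAMPLE_TOLERANCE_MIN = 1.0
BURST_GAP_FACTOR = 2.0
AGL_MIN_M = -50.0
AGL_MAX_M = 4000.0
INDEPENDENCE_RADIUS_KM = 10.0


class InputError(ValueError):
    """Malformed input table."""


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_fixes(path) -> pd.DataFrame:
    """Read a fix CSV into a typed, per-bird time-sorted table.

    Raises :class:`InputError` naming the offending row for a missing
    column or an unparsable timestamp; rows with unparsable numeric fields
    are dropped (and counted in the log).  Duplicate timestamps within a
    bird collapse to the first occurrence.
    """
    df = pd.read_csv(path, dtype={"bird_id": str, "fix_quality": str})
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"missing required column(s): {', '.join(missing)}")
    ts = pd.to_datetime(df["timestamp_utc"], errors="coerce", utc=True)
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise InputError(f"unparsable timestamp at row {row}: "
                         f"{df['timestamp_utc'].iloc[row]!r}")
    df = df.copy()
    df["timestamp_utc"] = ts.dt.tz_localize(None)

    n0 = len(df)
    for col in ("lon", "lat", "alt_asl_m", "hdop", "vdop"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["lon", "lat", "alt_asl_m", "hdop", "vdop"]].isna().any(axis=1)
    if bad.any():
        logger.info("read_fixes: dropped %d rows with unparsable numeric fields",
                    int(bad.sum()))
    df = df.loc[~bad]
    df["fix_quality"] = df["fix_quality"].str.upper().str.strip()

    df = df.sort_values(["bird_id", "timestamp_utc"], kind="mergesort")
    df = df.drop_duplicates(subset=["bird_id", "timestamp_utc"], keep="first")
    if "fix_id" not in df.columns:
        df = df.reset_index(drop=True)
        df.insert(0, "fix_id", np.arange(len(df)))
    dropped = n0 - len(df)
    if dropped:
        logger.info("read_fixes: %d of %d rows removed while reading", dropped, n0)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_quality(fixes: pd.DataFrame) -> pd.DataFrame:
    """Keep 3D fixes with HDOP < 10 and VDOP < 10."""
    keep = ((fixes["fix_quality"] == "3D")
            & (fixes["hdop"] < 10.0) & (fixes["vdop"] < 10.0))
    out = fixes.loc[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("filter_quality: no fixes survived the quality filter")
    return out


def subsample_interval(fixes: pd.DataFrame,
                       target_min: float = SUBSAMPLE_TARGET_MIN,
                       tolerance_min: float = SUBSAMPLE_TOLERANCE_MIN) -> pd.DataFrame:
    """Greedy subsampling to the target fix interval.

    Per bird: keep the first fix, then repeatedly keep the earliest fix at
    least ``target - tolerance`` after the last kept fix.  Data already at
    the target interval passes through unchanged.
    """
    min_gap = pd.Timedelta(minutes=target_min - tolerance_min)
    keep_idx: list[int] = []
    for _, g in fixes.groupby("bird_id", sort=False):
        t = g["timestamp_utc"]
        last = None
        for idx, ti in zip(g.index, t):
            if last is None or ti - last >= min_gap:
                keep_idx.append(idx)
                last = ti
    return fixes.loc[sorted(keep_idx)].reset_index(drop=True)


def solar_elevation_deg(lon, lat, times) -> np.ndarray:
    """Solar elevation (degrees, unrefracted) by the NOAA approximation."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    t = pd.DatetimeIndex(pd.to_datetime(times))
    jd = t.to_julian_date().to_numpy()
    T = (jd - 2451545.0) / 36525.0

    L0 = (280.46646 + T * (36000.76983 + 0.0003032 * T)) % 360.0
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)
    Mr = np.radians(M)
    C = (np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
         + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
         + np.sin(3 * Mr) * 0.000289)
    true_long = L0 + C
    omega = np.radians(125.04 - 1934.136 * T)
    lam = np.radians(true_long - 0.00569 - 0.00478 * np.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(eps) * np.sin(lam))

    y = np.tan(eps / 2.0) ** 2
    L0r = np.radians(L0)
    eqtime = 4.0 * np.degrees(
        y * np.sin(2 * L0r) - 2 * e * np.sin(Mr)
        + 4 * e * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r) - 1.25 * e * e * np.sin(2 * Mr))

    minutes = (t.hour * 60.0 + t.minute + t.second / 60.0
               + t.microsecond / 6.0e7).to_numpy()
    tst = (minutes + eqtime + 4.0 * lon) % 1440.0
    ha = np.radians(tst / 4.0 - 180.0)
    latr = np.radians(lat)
    sin_elev = (np.sin(latr) * np.sin(decl)
                + np.cos(latr) * np.cos(decl) * np.cos(ha))
    return np.degrees(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))


def filter_daylight(fixes: pd.DataFrame,
                    threshold_deg: float = CIVIL_TWILIGHT_DEG) -> pd.DataFrame:
    """Keep fixes between civil dawn and civil dusk (sun >= -6 degrees)."""
    if (fixes["lat"].abs() > 66.5).any():
        warnings.warn("fixes poleward of 66.5 degrees latitude: civil twilight "
                      "may be undefined; retaining fixes with sun above threshold")
    elev = solar_elevation_deg(fixes["lon"].to_numpy(), fixes["lat"].to_numpy(),
                               fixes["timestamp_utc"])
    return fixes.loc[elev >= threshold_deg].reset_index(drop=True)


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    a = (np.sin((lat2 - lat1) / 2) ** 2
         + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2)
    return 2.0 * 6371.0088 * np.arcsin(np.sqrt(a))


def filter_independence(fixes: pd.DataFrame, natal_nests=None,
                        radius_km: float = INDEPENDENCE_RADIUS_KM) -> pd.DataFrame:
    """Drop each hatch-year bird's fixes before its first move beyond the
    natal-nest radius; everything after the first exceedance is kept,
    including later returns.  Birds without a supplied nest pass through.
    """
    if natal_nests is None:
        return fixes
    if isinstance(natal_nests, pd.DataFrame):
        natal_nests = {r.bird_id: (r.lon, r.lat) for r in natal_nests.itertuples()}
    keep = np.ones(len(fixes), dtype=bool)
    pos = fixes.reset_index(drop=True)
    for bird, g in pos.groupby("bird_id", sort=False):
        if bird not in natal_nests:
            continue
        nlon, nlat = natal_nests[bird]
        d = haversine_km(g["lon"], g["lat"], nlon, nlat)
        beyond = np.flatnonzero(d > radius_km)
        if beyond.size == 0:
            keep[g.index] = False
            warnings.warn(f"bird {bird} never exceeded {radius_km} km from its "
                          "natal nest; all fixes dropped")
        else:
            keep[g.index[:beyond[0]]] = False
    return pos.loc[keep].reset_index(drop=True)


def compute_and_filter_agl(fixes: pd.DataFrame, dem: Raster,
                           agl_min: float = AGL_MIN_M,
                           agl_max: float = AGL_MAX_M) -> pd.DataFrame:
    """Compute AGL by bilinear DEM sampling and keep fixes in [min, max].

    AGL = telemetry altitude ASL minus ground elevation.  Fixes outside the
    DEM extent are dropped (counted in the log); the stated bounds are kept
    inclusive (exactly -50 m and 4,000 m survive).
    """
    if dem.grid is None:
        raise InputError("DEM has no lon/lat anchor; cannot project fixes")
    x, y = dem.grid.lonlat_to_xy(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    ground, inside = dem.sample(x, y, method="bilinear")
    if (~inside).any():
        logger.info("compute_and_filter_agl: %d fixes outside the DEM extent dropped",
                    int((~inside).sum()))
    agl = fixes["alt_asl_m"].to_numpy(dtype=float) - ground
    # bounds are inclusive; the epsilon keeps exact-boundary AGLs from being
    # dropped by projection round-trip noise
    eps = 1e-6
    keep = inside & (agl >= agl_min - eps) & (agl <= agl_max + eps)
    out = fixes.loc[keep].reset_index(drop=True).copy()
    out["x"] = x[keep]
    out["y"] = y[keep]
    out["elev_ground_m"] = ground[keep]
    out["agl_m"] = agl[keep]
    return out


# ---------------------------------------------------------------------------
# step metrics
# ---------------------------------------------------------------------------

def derive_steps(points: pd.DataFrame,
                 nominal_interval_min: float = SUBSAMPLE_TARGET_MIN,
                 gap_factor: float = BURST_GAP_FACTOR) -> pd.DataFrame:
    """Per-step speed, turning angle, and persistence velocity.

    One row per step (consecutive point pair within a burst).  Turning
    angle at a step is the heading change from the previous step; the first
    step of each burst (and any step after a zero-length step) carries
    turn = 0 with ``turn_defined = False``.  Vp = speed * cos(turn).
    """
    gap = pd.Timedelta(minutes=nominal_interval_min * gap_factor)
    rows = []
    burst_id = -1
    for bird, g in points.groupby("bird_id", sort=False):
        g = g.sort_values("timestamp_utc")
        t = g["timestamp_utc"].to_numpy()
        x = g["x"].to_numpy(dtype=float)
        y = g["y"].to_numpy(dtype=float)
        agl = g["agl_m"].to_numpy(dtype=float) if "agl_m" in g else np.full(len(g), np.nan)
        fid = g["fix_id"].to_numpy() if "fix_id" in g else g.index.to_numpy()
        dt = np.diff(t).astype("timedelta64[s]").astype(float)
        new_burst = np.concatenate([[True], dt > gap.total_seconds()])
        i = 0
        n = len(g)
        while i < n:
            j = i + 1
            while j < n and not new_burst[j]:
                j += 1
            # burst spans points i..j-1
            if j - i >= 2:
                burst_id += 1
                prev_heading = np.nan
                for kk in range(i, j - 1):
                    dxy = (x[kk + 1] - x[kk], y[kk + 1] - y[kk])
                    dt_h = (t[kk + 1] - t[kk]) / np.timedelta64(1, "h")
                    dist_m = math.hypot(*dxy)
                    speed = dist_m / 1000.0 / dt_h
                    if dist_m > 0:
                        heading = math.atan2(dxy[0], dxy[1])
                        zero_step = False
                    else:
                        heading = prev_heading     # undefined; carry forward
                        zero_step = True
                    if not math.isnan(prev_heading) and not zero_step:
                        turn = math.degrees(
                            (heading - prev_heading + math.pi) % (2 * math.pi) - math.pi)
                        turn_defined = True
                    else:
                        turn = 0.0
                        turn_defined = False
                    vp = speed * math.cos(math.radians(turn))
                    rows.append((fid[kk], bird, t[kk], x[kk], y[kk], dt_h,
                                 speed, turn, abs(turn), turn_defined, vp,
                                 agl[kk], burst_id))
                    if not zero_step:
                        prev_heading = heading
            i = j
    steps = pd.DataFrame(rows, columns=[
        "fix_id", "bird_id", "t", "x", "y", "dt_h", "speed_kmh",
        "turn_deg", "turn_abs_deg", "turn_defined", "vp_kmh", "agl_m", "burst"])
    steps.index.name = "step_idx"
    return steps.reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    points: pd.DataFrame
    steps: pd.DataFrame
    ledger: dict = field(default_factory=dict)


def run_preprocess(fixes: pd.DataFrame, dem: Raster,
                   natal_nests=None,
                   target_interval_min: float = SUBSAMPLE_TARGET_MIN,
                   agl_min: float = AGL_MIN_M,
                   agl_max: float = AGL_MAX_M) -> PreprocessResult:
    """Apply the full filter chain and derive the step series.

    The ledger records the rows removed by each stage; the counts sum
    exactly to input minus output.
    """
    ledger: dict[str, int] = {"input": len(fixes)}
    fixes = fixes.sort_values(["bird_id", "timestamp_utc"],
                              kind="mergesort").reset_index(drop=True)
    cur = filter_quality(fixes)
    ledger["removed_quality"] = ledger["input"] - len(cur)
    n = len(cur)
    cur = subsample_interval(cur, target_min=target_interval_min)
    ledger["removed_subsample"] = n - len(cur)
    n = len(cur)
    cur = filter_daylight(cur)
    ledger["removed_daylight"] = n - len(cur)
    n = len(cur)
    cur = filter_independence(cur, natal_nests)
    ledger["removed_independence"] = n - len(cur)
    n = len(cur)
    points = compute_and_filter_agl(cur, dem, agl_min=agl_min, agl_max=agl_max)
    ledger["removed_agl"] = n - len(points)
    ledger["output"] = len(points)
    steps = derive_steps(points, nominal_interval_min=target_interval_min)
    return PreprocessResult(points=points, steps=steps, ledger=ledger)
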