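"""Behavioral change point analysis (BCPA) on persistence velocity.

The persistence-velocity series within a burst is modeled as a Gaussian
process with mean mu, standard deviation sigma, and autocorrelation rho per
nominal fix interval; gaps enter as real-valued exponents, i.e. the
conditional law of X_i given X_{i-1} is

    Normal(mu + rho**dt_i * (X_{i-1} - mu), sigma**2 * (1 - rho**(2*dt_i)))

with the first point of a burst marginal Normal(mu, sigma**2).  A 30-point
window sweeps each burst; within a window, eight models M0..M7 (every
subset of {mu, sigma, rho} changing at a candidate break) are fitted by
maximum likelihood and compared by BIC, the break location counting as one
parameter.  Non-null windows vote for break positions, which are
consolidated into changepoints by clustering votes and requiring minimum
support; segments are the runs between consecutive changepoints.

For a fixed rho the remaining parameters profile in closed form, so the
window fits reduce to a search over rho (a grid inside windows, a bounded
scalar optimization in :func:`fit_msr`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

WINDOW_DEFAULT = 30
EDGE_BUFFER = 5
SWEEP_STEP = 1
CLUSTER_WIDTH = 4
MIN_SUPPORT = 3
DBIC_MIN = 10.0
RHO_MAX = 0.999
RHO_GRID = np.concatenate([np.linspace(0.0, 0.9, 19), [0.95, 0.99]])

MODEL_NAMES = {0: "M0", 1: "M1:mu", 2: "M2:sigma", 3: "M3:rho", 4: "M4:mu+sigma",
               5: "M5:mu+rho", 6: "M6:sigma+rho", 7: "M7:mu+sigma+rho"}
# BIC parameter count: 3 baseline; +|changed set| +1 for the break location
MODEL_K = {0: 3, 1: 5, 2: 5, 3: 5, 4: 6, 5: 6, 6: 6, 7: 7}

_RSS_FLOOR = 1e-12


@dataclass
class MsrParams:
    mu: float
    sigma: float
    rho: float
    loglik: float


@dataclass
class WindowResult:
    start: int                  # index of the window's first point
    model: int                  # 0..7
    break_index: int | None     # absolute index of first point of right regime
    dbic: float                 # BIC(M0) - BIC(best); 0 when M0 selected
    left: MsrParams | None = None
    right: MsrParams | None = None


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _suff_stats(x: np.ndarray, delta: np.ndarray, rho: float):
    """(A, B, C, L, m) for one series at one rho; first point marginal.

    With a_i = rho**delta_i, y_i = x_i - a_i x_{i-1}, c_i = 1 - a_i,
    v_i = 1 - a_i**2, the profile quantities are A = sum(y c / v),
    B = sum(c^2 / v), C = sum(y^2 / v), L = sum(log v).
    """
    n = len(x)
    if n == 0:
        return 0.0, 0.0, 0.0, 0.0, 0
    if rho <= 0.0:
        y = x
        A = float(np.sum(y))
        B = float(n)
        C = float(np.sum(y * y))
        return A, B, C, 0.0, n
    a = rho ** delta[1:]
    y = x[1:] - a * x[:-1]
    c = 1.0 - a
    v = 1.0 - a * a
    v = np.maximum(v, 1e-300)
    A = x[0] + float(np.sum(y * c / v))
    B = 1.0 + float(np.sum(c * c / v))
    C = x[0] ** 2 + float(np.sum(y * y / v))
    L = float(np.sum(np.log(v)))
    return A, B, C, L, n


def _profile_loglik(A, B, C, L, m):
    """Maximized log-likelihood with free mu and sigma given the stats."""
    mu = A / B
    rss = max(C - A * A / B, _RSS_FLOOR)
    sigma2 = rss / m
    ll = -0.5 * m * math.log(2.0 * math.pi * sigma2) - 0.5 * L - 0.5 * m
    return ll, mu, math.sqrt(sigma2)


def fit_msr(x, dt=None, dt_nominal: float = 1.0) -> MsrParams:
    """Maximum-likelihood (mu, sigma, rho) for one stationary series.

    ``dt`` are the time gaps before each point (the first entry is
    ignored), expressed in the same units as ``dt_nominal``; rho is
    parameterized per nominal interval.  mu and sigma are profiled in
    closed form at each rho and rho is found by bounded scalar search
    (the rho = 0 endpoint is checked explicitly, where the likelihood is
    exactly the iid Gaussian one).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 points to fit the movement model")
    delta = (np.ones(n) if dt is None
             else np.asarray(dt, dtype=float) / dt_nominal)

    if np.ptp(x) == 0.0:
        warnings.warn("constant series: sigma is degenerate, returning floor")
        return MsrParams(mu=float(x[0]), sigma=math.sqrt(_RSS_FLOOR / n), rho=0.0,
                         loglik=_profile_loglik(*_suff_stats(x, delta, 0.0))[0])

    def neg_ll(rho: float) -> float:
        return -_profile_loglik(*_suff_stats(x, delta, rho))[0]

    res = minimize_scalar(neg_ll, bounds=(0.0, RHO_MAX), method="bounded",
                          options={"xatol": 1e-6})
    rho = float(res.x)
    if neg_ll(0.0) <= res.fun:
        rho = 0.0
    ll, mu, sigma = _profile_loglik(*_suff_stats(x, delta, rho))
    return MsrParams(mu=mu, sigma=sigma, rho=rho, loglik=ll)


# ---------------------------------------------------------------------------
# windowed most-likely-changepoint search
# ---------------------------------------------------------------------------

def _grid_prefix_stats(x: np.ndarray, delta: np.ndarray, grid: np.ndarray):
    """Per-rho prefix sums of the conditional-term statistics.

    Returns arrays of shape (m, n) whose entry [r, j] sums conditional
    terms i = 1..j (entry j = 0 is zero).
    """
    m = len(grid)
    n = len(x)
    a = grid[:, None] ** delta[None, 1:]          # (m, n-1)
    y = x[None, 1:] - a * x[None, :-1]
    c = 1.0 - a
    v = np.maximum(1.0 - a * a, 1e-300)
    inv = 1.0 / v
    zeros = np.zeros((m, 1))
    PA = np.concatenate([zeros, np.cumsum(y * c * inv, axis=1)], axis=1)
    PB = np.concatenate([zeros, np.cumsum(c * c * inv, axis=1)], axis=1)
    PC = np.concatenate([zeros, np.cumsum(y * y * inv, axis=1)], axis=1)
    PL = np.concatenate([zeros, np.cumsum(np.log(v), axis=1)], axis=1)
    return PA, PB, PC, PL


def _own_sigma_ll(A, B, C, L, m):
    rss = np.maximum(C - A * A / B, _RSS_FLOOR)
    s2 = rss / m
    return -0.5 * m * np.log(2.0 * math.pi * s2) - 0.5 * L - 0.5 * m


def _shared_mu_iter(AL, BL, CL, mL, AR, BR, CR, mR, iters=4):
    """Iteratively reweighted shared-mu fit with per-side sigma.

    Returns (rssL, rssR) at the final mu (arrays broadcast over inputs).
    """
    mu = (AL + AR) / (BL + BR)
    for _ in range(iters):
        rssL = np.maximum(CL - 2 * mu * AL + mu * mu * BL, _RSS_FLOOR)
        rssR = np.maximum(CR - 2 * mu * AR + mu * mu * BR, _RSS_FLOOR)
        wL = mL / rssL
        wR = mR / rssR
        mu = (wL * AL + wR * AR) / (wL * BL + wR * BR)
    rssL = np.maximum(CL - 2 * mu * AL + mu * mu * BL, _RSS_FLOOR)
    rssR = np.maximum(CR - 2 * mu * AR + mu * mu * BR, _RSS_FLOOR)
    return rssL, rssR


def window_mlcp(x, dt=None, dt_nominal: float = 1.0, edge: int = EDGE_BUFFER,
                rho_grid: np.ndarray | None = None, offset: int = 0) -> WindowResult:
    """Most likely change point within one window by BIC over M0..M7.

    Candidate breaks keep at least ``edge`` points on each side.  Returns
    the BIC-minimizing model with its break (``model = 0`` means no change
    point).  ``offset`` shifts reported indices to absolute positions.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    grid = RHO_GRID if rho_grid is None else np.asarray(rho_grid, dtype=float)
    if n < 2 * edge + 1:
        raise ValueError("window shorter than twice the edge buffer")
    delta = (np.ones(n) if dt is None
             else np.asarray(dt, dtype=float) / dt_nominal)
    m = len(grid)
    breaks = np.arange(edge, n - edge + 1)        # first index of right regime
    nb = len(breaks)

    PA, PB, PC, PL = _grid_prefix_stats(x, delta, grid)
    totA, totB, totC, totL = PA[:, -1], PB[:, -1], PC[:, -1], PL[:, -1]

    # left side: marginal at 0 plus conditionals 1..b-1  -> shape (m, nb)
    AL = x[0] + PA[:, breaks - 1]
    BL = 1.0 + PB[:, breaks - 1]
    CL = x[0] ** 2 + PC[:, breaks - 1]
    LL = PL[:, breaks - 1]
    mLn = breaks.astype(float)[None, :]
    # right side: marginal at b plus conditionals b+1..n-1
    AR = x[breaks][None, :] + (totA[:, None] - PA[:, breaks])
    BR = 1.0 + (totB[:, None] - PB[:, breaks])
    CR = (x[breaks] ** 2)[None, :] + (totC[:, None] - PC[:, breaks])
    LR = totL[:, None] - PL[:, breaks]
    mRn = (n - breaks).astype(float)[None, :]

    # M0: single regime over the whole window
    A0 = x[0] + totA
    B0 = 1.0 + totB
    C0 = x[0] ** 2 + totC
    ll0 = float(np.max(_own_sigma_ll(A0, B0, C0, totL, float(n))))
    bic = {0: -2.0 * ll0 + MODEL_K[0] * math.log(n)}
    best_b = {0: None}

    def _record(model: int, ll_over_b: np.ndarray) -> None:
        i = int(np.argmax(ll_over_b))
        ll = float(ll_over_b[i])
        bic[model] = -2.0 * ll + MODEL_K[model] * math.log(n)
        best_b[model] = int(breaks[i])

    rssL_free = np.maximum(CL - AL * AL / BL, _RSS_FLOOR)
    rssR_free = np.maximum(CR - AR * AR / BR, _RSS_FLOOR)

    # --- shared-rho models: arrays (m, nb), maximize over rho then b
    # M1: mu splits; sigma, rho shared
    s2 = (rssL_free + rssR_free) / n
    ll1 = -0.5 * n * np.log(2 * math.pi * s2) - 0.5 * (LL + LR) - 0.5 * n
    _record(1, ll1.max(axis=0))
    # M2: sigma splits; mu, rho shared
    rssL2, rssR2 = _shared_mu_iter(AL, BL, CL, mLn, AR, BR, CR, mRn)
    ll2 = (-0.5 * mLn * np.log(2 * math.pi * rssL2 / mLn) - 0.5 * LL - 0.5 * mLn
           - 0.5 * mRn * np.log(2 * math.pi * rssR2 / mRn) - 0.5 * LR - 0.5 * mRn)
    _record(2, ll2.max(axis=0))
    # M4: mu and sigma split; rho shared
    ll4 = (_own_sigma_ll(AL, BL, CL, LL, mLn) + _own_sigma_ll(AR, BR, CR, LR, mRn))
    _record(4, ll4.max(axis=0))

    # --- split-rho models: broadcast left rho x right rho -> (m, m, nb)
    AL3, BL3, CL3, LL3 = (t[:, None, :] for t in (AL, BL, CL, LL))
    AR3, BR3, CR3, LR3 = (t[None, :, :] for t in (AR, BR, CR, LR))
    mL3 = mLn[None, :, :]
    mR3 = mRn[None, :, :]
    # M3: rho splits; mu, sigma shared
    mu3 = (AL3 + AR3) / (BL3 + BR3)
    rss3 = (np.maximum(CL3 - 2 * mu3 * AL3 + mu3 ** 2 * BL3, _RSS_FLOOR)
            + np.maximum(CR3 - 2 * mu3 * AR3 + mu3 ** 2 * BR3, _RSS_FLOOR))
    ll3 = -0.5 * n * np.log(2 * math.pi * rss3 / n) - 0.5 * (LL3 + LR3) - 0.5 * n
    _record(3, ll3.max(axis=(0, 1)))
    # M5: mu and rho split; sigma shared
    rss5 = rssL_free[:, None, :] + rssR_free[None, :, :]
    ll5 = -0.5 * n * np.log(2 * math.pi * rss5 / n) - 0.5 * (LL3 + LR3) - 0.5 * n
    _record(5, ll5.max(axis=(0, 1)))
    # M6: sigma and rho split; mu shared
    rssL6, rssR6 = _shared_mu_iter(AL3, BL3, CL3, mL3, AR3, BR3, CR3, mR3)
    ll6 = (-0.5 * mL3 * np.log(2 * math.pi * rssL6 / mL3) - 0.5 * LL3 - 0.5 * mL3
           - 0.5 * mR3 * np.log(2 * math.pi * rssR6 / mR3) - 0.5 * LR3 - 0.5 * mR3)
    _record(6, ll6.max(axis=(0, 1)))
    # M7: everything splits; sides maximize independently
    ll7 = (_own_sigma_ll(AL, BL, CL, LL, mLn).max(axis=0)
           + _own_sigma_ll(AR, BR, CR, LR, mRn).max(axis=0))
    _record(7, ll7)

    sel = min(bic, key=lambda mdl: (bic[mdl], mdl))
    dbic = bic[0] - bic[sel]
    if sel == 0 or dbic <= 0.0:
        full = fit_msr(x, dt=delta, dt_nominal=1.0)
        return WindowResult(start=offset, model=0, break_index=None, dbic=0.0,
                            left=full, right=full)
    b = best_b[sel]
    left = fit_msr(x[:b], dt=delta[:b], dt_nominal=1.0)
    right = fit_msr(x[b:], dt=delta[b:], dt_nominal=1.0)
    return WindowResult(start=offset, model=sel, break_index=offset + b,
                        dbic=float(dbic), left=left, right=right)


# ---------------------------------------------------------------------------
# sweep, consolidation, segmentation
# ---------------------------------------------------------------------------

def sweep(steps: pd.DataFrame, window: int = WINDOW_DEFAULT, step: int = SWEEP_STEP,
          edge: int = EDGE_BUFFER, nominal_interval_min: float = 15.0,
          rho_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Slide the changepoint window across every burst.

    ``steps`` needs columns ``vp_kmh``, ``dt_h``, ``burst`` (and is indexed
    by consecutive step position).  Bursts shorter than the window yield no
    windows.  Returns one row per evaluated window with the selected model
    and (absolute) break index; deterministic.
    """
    rows = []
    vp_all = steps["vp_kmh"].to_numpy(dtype=float)
    dt_all = steps["dt_h"].to_numpy(dtype=float) * (60.0 / nominal_interval_min)
    burst_all = steps["burst"].to_numpy()
    for burst in pd.unique(burst_all):
        idx = np.flatnonzero(burst_all == burst)
        nb = len(idx)
        if nb < window:
            continue
        x = vp_all[idx]
        # gap before point i within the burst is the previous step's duration
        delta = np.ones(nb)
        delta[1:] = dt_all[idx[:-1]]
        for s in range(0, nb - window + 1, step):
            res = window_mlcp(x[s:s + window], dt=delta[s:s + window],
                              dt_nominal=1.0, edge=edge, rho_grid=rho_grid,
                              offset=int(idx[0]) + s)
            rows.append((int(idx[0]) + s, int(burst), res.model,
                         -1 if res.break_index is None else int(res.break_index),
                         res.dbic))
    return pd.DataFrame(rows, columns=["start", "burst", "model",
                                       "break_idx", "dbic"])


def consolidate(window_results: pd.DataFrame, cluster_width: int = CLUSTER_WIDTH,
                min_support: int = MIN_SUPPORT,
                dbic_min: float = DBIC_MIN) -> pd.DataFrame:
    """Cluster per-window break votes into changepoints.

    Within each burst, sorted break indices from non-null windows whose BIC
    improvement is at least ``dbic_min`` are agglomerated into groups whose
    consecutive members differ by at most ``cluster_width``; groups with at
    least ``min_support`` votes become one changepoint at the group's
    median index (ties to the lower index).  The vote-strength floor and
    support default are calibrated so that a stationary autocorrelated
    series yields essentially no changepoints while a 4-sigma mean shift is
    almost always recovered.
    """
    rows = []
    nz = window_results[(window_results["model"] != 0)
                        & (window_results["dbic"] >= dbic_min)]
    for burst, g in nz.groupby("burst", sort=True):
        breaks = np.sort(g["break_idx"].to_numpy())
        if len(breaks) == 0:
            continue
        group = [breaks[0]]
        groups = []
        for b in breaks[1:]:
            if b - group[-1] <= cluster_width:
                group.append(b)
            else:
                groups.append(group)
                group = [b]
        groups.append(group)
        for grp in groups:
            if len(grp) >= min_support:
                arr = np.asarray(grp)
                cp = int(arr[(len(arr) - 1) // 2])   # median; ties -> lower
                rows.append((int(burst), cp, len(grp)))
    return pd.DataFrame(rows, columns=["burst", "break_idx", "support"])


def segment_track(steps: pd.DataFrame,
                  changepoints: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cut each burst at its changepoints.

    Returns ``(segments, steps_with_seg)``: segments partition every burst
    (a burst without changepoints is one segment) and each step gains a
    ``seg_id`` column.
    """
    steps = steps.reset_index(drop=True)
    seg_of_step = np.full(len(steps), -1, dtype=int)
    seg_rows = []
    seg_id = 0
    burst_all = steps["burst"].to_numpy()
    for burst in pd.unique(burst_all):
        idx = np.flatnonzero(burst_all == burst)
        cps = (changepoints.loc[changepoints["burst"] == burst, "break_idx"]
               .sort_values().to_numpy()
               if len(changepoints) else np.array([], dtype=int))
        cps = cps[(cps > idx[0]) & (cps <= idx[-1])]
        bounds = np.concatenate([[idx[0]], cps, [idx[-1] + 1]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b <= a:
                continue
            sl = steps.iloc[a:b]
            seg_rows.append((sl["bird_id"].iloc[0], seg_id, int(burst),
                             int(a), int(b - 1), sl["t"].iloc[0],
                             sl["t"].iloc[-1], int(b - a)))
            seg_of_step[a:b] = seg_id
            seg_id += 1
    segments = pd.DataFrame(seg_rows, columns=[
        "bird_id", "seg_id", "burst", "start_step", "end_step",
        "t_start", "t_end", "n_points"])
    out = steps.copy()
    out["seg_id"] = seg_of_step
    return segments, out


@dataclass
class SegmentationResult:
    segments: pd.DataFrame
    steps: pd.DataFrame           # with seg_id
    changepoints: pd.DataFrame
    windows: pd.DataFrame
    params: dict = field(default_factory=dict)


def run_segmentation(steps: pd.DataFrame, window: int = WINDOW_DEFAULT,
                     step: int = SWEEP_STEP, edge: int = EDGE_BUFFER,
                     cluster_width: int = CLUSTER_WIDTH,
                     min_support: int = MIN_SUPPORT,
                     dbic_min: float = DBIC_MIN,
                     nominal_interval_min: float = 15.0) -> SegmentationResult:
    """Sweep, consolidate, and segment in one call."""
    windows = sweep(steps, window=window, step=step, edge=edge,
                    nominal_interval_min=nominal_interval_min)
    cps = consolidate(windows, cluster_width=cluster_width,
                      min_support=min_support, dbic_min=dbic_min)
    segments, steps_out = segment_track(steps, cps)
    return SegmentationResult(segments=segments, steps=steps_out,
                              changepoints=cps, windows=windows,
                              params={"window": window, "step": step,
                                      "edge": edge,
                                      "cluster_width": cluster_width,
                                      "min_support": min_support})


def window_sensitivity(steps: pd.DataFrame,
                       windows: tuple[int, ...] = (WINDOW_DEFAULT,
                                                   2 * WINDOW_DEFAULT),
                       **kwargs) -> dict[int, int]:
    """Diagnostic: segment counts under alternative window sizes."""
    out = {}
    for w in windows:
        res = run_segmentation(steps, window=w, **kwargs)
        out[w] = len(res.segments)
    return out
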