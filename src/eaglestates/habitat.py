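"""Paired mixed-logistic habitat models with AICc multimodel averaging.

Three binomial-logit contrasts are fitted per dataset: low-altitude states
(1 & 2) versus high (3 & 4); state 1 versus 2 within the low band; state 3
versus 4 within the high band.  Every model carries crossed random
intercepts for bird identity and calendar month, fitted by
Laplace-approximate maximum likelihood (penalized IRLS for the modes, a
Nelder-Mead search over the two log-SDs).  Continuous predictors are
rescaled to mean 0, sd 0.5 (centering and dividing by twice the sample
standard deviation) so coefficients are comparable across predictors;
reference levels are canyon (TPI), forest (land cover), and adult (age).

Candidate fixed-effect subsets are ranked by AICc (categorical terms enter
or leave as blocks; random effects are present in every model) and models
with Akaike weight >= 0.01 are combined by full (zero-substitution)
averaging with the unconditional standard error that includes
between-model variance.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

logger = logging.getLogger(__name__)

WEIGHT_FLOOR = 0.01
SD_FLOOR = 1e-4          # random-intercept SD floor keeps degenerate fits finite
SD_CEIL = 25.0

CONTINUOUS_TERMS = ("elevation", "northness", "eastness", "slope")
TERM_COLUMNS = {
    "elevation": ["elevation"],
    "northness": ["northness"],
    "eastness": ["eastness"],
    "slope": ["slope"],
    "age": ["age_preadult"],
    "landcover": ["landcover_semidesert", "landcover_rockveg",
                  "landcover_shrubgrass"],
    "tpi": ["tpi_steep", "tpi_gentle", "tpi_ridge"],
}
CANDIDATE_TERMS = ("elevation", "eastness", "northness", "slope",
                   "tpi", "landcover", "age")


class FitError(RuntimeError):
    """Mixed-model fit failed to converge."""


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GelmanScale:
    mean: float
    sd: float          # sample sd (ddof = 1)

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / (2.0 * self.sd)


def rescale_gelman(x, scale: GelmanScale | None = None, name: str = "x"):
    """Center and divide by twice the sample sd; returns (x', scale).

    Passing a previously fitted ``scale`` reapplies the stored transform
    (for prediction on new data).  A constant column is an error.
    """
    x = np.asarray(x, dtype=float)
    if scale is None:
        sd = float(np.std(x, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"cannot rescale constant column {name!r}")
        scale = GelmanScale(mean=float(np.mean(x)), sd=sd)
    return scale.apply(x), scale


# ---------------------------------------------------------------------------
# modeling frames
# ---------------------------------------------------------------------------

def _age_class(years: pd.Series) -> np.ndarray:
    """Adult after the fourth year; ages increment each January because age
    is a difference of calendar years."""
    return np.where(years >= 5, "adult", "preadult")


def build_frames(points: pd.DataFrame, bird_meta: pd.DataFrame | None = None,
                 covariates: tuple = CONTINUOUS_TERMS) -> dict[str, pd.DataFrame]:
    """Assemble the three paired-contrast modeling frames.

    ``points`` is a per-fix table with ``state``, the continuous covariates
    (raw units), integer ``landcover`` and ``tpi_class`` codes, ``bird_id``
    and timestamp ``t``.  Continuous covariates are Gelman-rescaled within
    each frame.  Frames with fewer than two response classes are skipped
    with a warning.
    """
    pts = points.copy()
    pts = pts.dropna(subset=list(covariates) + ["landcover", "tpi_class", "state"])
    t = pd.to_datetime(pts["t"])
    pts["month"] = t.dt.month
    if bird_meta is not None:
        hatch = dict(zip(bird_meta["bird_id"], bird_meta["hatch_year"]))
        age_years = t.dt.year - pts["bird_id"].map(hatch)
        pts["age"] = _age_class(age_years)
    else:
        pts["age"] = "adult"

    pts["age_preadult"] = (pts["age"] == "preadult").astype(float)
    lc = pts["landcover"].astype(int)
    pts["landcover_semidesert"] = (lc == 1).astype(float)
    pts["landcover_rockveg"] = (lc == 3).astype(float)
    pts["landcover_shrubgrass"] = (lc == 4).astype(float)
    tc = pts["tpi_class"].astype(int)
    pts["tpi_steep"] = (tc == 2).astype(float)
    pts["tpi_gentle"] = (tc == 3).astype(float)
    pts["tpi_ridge"] = (tc == 4).astype(float)

    specs = {
        "lowhigh": (pts["state"].isin([1, 2, 3, 4]), pts["state"].isin([1, 2])),
        "s1v2": (pts["state"].isin([1, 2]), pts["state"] == 1),
        "s3v4": (pts["state"].isin([3, 4]), pts["state"] == 3),
    }
    keep_cols = (list(covariates) + ["age_preadult", "landcover_semidesert",
                                     "landcover_rockveg", "landcover_shrubgrass",
                                     "tpi_steep", "tpi_gentle", "tpi_ridge",
                                     "bird_id", "month"])
    frames = {}
    for name, (rows, positive) in specs.items():
        sub = pts.loc[rows, keep_cols].copy()
        sub["response"] = positive.loc[rows].astype(int)
        if sub["response"].nunique() < 2:
            warnings.warn(f"frame {name!r} has fewer than two response "
                          "classes; skipped")
            continue
        for cov in covariates:
            sub[cov], _ = rescale_gelman(sub[cov].to_numpy(), name=cov)
        frames[name] = sub.reset_index(drop=True)
    return frames


# ---------------------------------------------------------------------------
# Laplace-ML mixed logistic regression
# ---------------------------------------------------------------------------

def _design(frame: pd.DataFrame, terms: tuple[str, ...]):
    cols = ["(Intercept)"]
    X = [np.ones(len(frame))]
    for term in terms:
        for c in TERM_COLUMNS[term]:
            cols.append(c)
            X.append(frame[c].to_numpy(dtype=float))
    X = np.column_stack(X)
    bird_codes, bird_levels = pd.factorize(frame["bird_id"], sort=True)
    month_codes, month_levels = pd.factorize(frame["month"], sort=True)
    return X, cols, bird_codes, len(bird_levels), month_codes, len(month_levels)


def _inner_newton(D: np.ndarray, y: np.ndarray, pen: np.ndarray,
                  w0: np.ndarray, max_iter: int = 60, tol: float = 1e-9):
    """Penalized IRLS/Newton for the joint (beta, u) modes.

    Returns (w, unpenalized loglik, Hessian D'WD + diag(pen)).
    """
    w = w0.copy()

    def parts(wv):
        eta = D @ wv
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))
        return mu, ll - 0.5 * float(pen @ (wv * wv))

    mu, obj = parts(w)
    for _ in range(max_iter):
        grad = D.T @ (y - mu) - pen * w
        Wd = np.clip(mu * (1 - mu), 1e-10, None)
        H = (D * Wd[:, None]).T @ D
        H[np.diag_indices_from(H)] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular Hessian in mixed-logit inner loop") from exc
        t = 1.0
        for _ in range(30):
            w_new = w + t * step
            mu_new, obj_new = parts(w_new)
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            t *= 0.5
        else:
            raise FitError("line search failed in mixed-logit inner loop")
        moved = float(np.max(np.abs(t * step)))
        w, mu, obj_prev, obj = w_new, mu_new, obj, obj_new
        if abs(obj - obj_prev) < tol * (1 + abs(obj)) and moved < 1e-6:
            break
    else:
        raise FitError("mixed-logit inner loop did not converge")
    eta = D @ w
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    ll = float(y @ np.log(mu) + (1 - y) @ np.log1p(-mu))
    Wd = np.clip(mu * (1 - mu), 1e-10, None)
    H = (D * Wd[:, None]).T @ D
    H[np.diag_indices_from(H)] += pen
    return w, ll, H


@dataclass
class ModelFit:
    terms: tuple
    coef: pd.Series
    se: pd.Series
    re_sd: dict
    loglik: float
    k: int
    n: int
    aicc: float
    delta_aicc: float = float("nan")
    weight: float = float("nan")


def fit_mixed_logistic(frame: pd.DataFrame, terms: tuple[str, ...] = CANDIDATE_TERMS,
                       max_retries: int = 5, nm_maxfev: int | None = None,
                       theta0: tuple[float, float] | None = None) -> ModelFit:
    """Binomial-logit model with crossed bird and month random intercepts.

    Fitted by Laplace-approximate maximum likelihood: the random-effect
    modes and fixed effects are found by penalized Newton iterations inside
    a Nelder-Mead search over the two log random-intercept SDs.  Returns
    coefficient estimates with Wald standard errors (conditional on the
    variance estimates), the Laplace log-likelihood, and AICc with
    k = (number of fixed effects) + 2 variance components and n = rows.
    """
    terms = tuple(terms)
    y = frame["response"].to_numpy(dtype=float)
    X, cols, bcode, qb, mcode, qm = _design(frame, terms)
    n, p = X.shape
    q = qb + qm
    Zb = np.zeros((n, qb))
    Zb[np.arange(n), bcode] = 1.0
    Zm = np.zeros((n, qm))
    Zm[np.arange(n), mcode] = 1.0
    D = np.concatenate([X, Zb, Zm], axis=1)

    state = {"w": np.zeros(p + q)}

    def neg_laplace(theta: np.ndarray) -> float:
        sb = float(np.clip(np.exp(theta[0]), SD_FLOOR, SD_CEIL))
        sm = float(np.clip(np.exp(theta[1]), SD_FLOOR, SD_CEIL))
        pen = np.concatenate([np.zeros(p), np.full(qb, 1.0 / sb ** 2),
                              np.full(qm, 1.0 / sm ** 2)])
        try:
            w, ll, H = _inner_newton(D, y, pen, state["w"])
        except FitError:
            return 1e12
        state["w"] = w
        u = w[p:]
        quad = float(np.sum(u[:qb] ** 2) / sb ** 2 + np.sum(u[qb:] ** 2) / sm ** 2)
        sign, logdet = np.linalg.slogdet(H[p:, p:])
        if sign <= 0:
            return 1e12
        lap = (ll - 0.5 * quad - 0.5 * logdet
               - 0.5 * (qb * math.log(sb ** 2) + qm * math.log(sm ** 2)))
        return -lap

    start = np.array(theta0 if theta0 is not None else (math.log(0.5), math.log(0.5)))
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_retries):
        x0 = start if attempt == 0 else start + rng.normal(0, 0.7, 2)
        res = minimize(neg_laplace, x0, method="Nelder-Mead",
                       options={"xatol": 2e-3, "fatol": 1e-6,
                                "maxfev": nm_maxfev or 200})
        if np.isfinite(res.fun) and res.fun < 1e11:
            best = res
            break
    if best is None:
        raise FitError("mixed-logit fit failed from all starts")

    theta = best.x
    sb = float(np.clip(np.exp(theta[0]), SD_FLOOR, SD_CEIL))
    sm = float(np.clip(np.exp(theta[1]), SD_FLOOR, SD_CEIL))
    pen = np.concatenate([np.zeros(p), np.full(qb, 1.0 / sb ** 2),
                          np.full(qm, 1.0 / sm ** 2)])
    w, _, H = _inner_newton(D, y, pen, state["w"])
    cov = np.linalg.inv(H)
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    loglik = -float(best.fun)
    k = p + 2
    return ModelFit(terms=terms,
                    coef=pd.Series(w[:p], index=cols),
                    se=pd.Series(se, index=cols),
                    re_sd={"bird": sb, "month": sm},
                    loglik=loglik, k=k, n=n,
                    aicc=aicc(loglik, k, n))


# ---------------------------------------------------------------------------
# information criteria, dredge, averaging
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n = {n} <= k + 1 = {k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def dredge_aicc(frame: pd.DataFrame,
                candidate_terms: tuple[str, ...] = CANDIDATE_TERMS,
                nm_maxfev: int | None = None) -> list[ModelFit]:
    """All-subsets fixed-effect search ranked by AICc.

    Categorical terms enter or leave as whole dummy blocks; the two random
    intercepts are present in every model.  Failed fits are logged and the
    ranking covers the remainder.  Duplicate term sets are fitted once.
    """
    candidate_terms = tuple(dict.fromkeys(candidate_terms))
    if len(candidate_terms) > 8:
        raise ValueError("at most 8 candidate terms are supported")
    full = fit_mixed_logistic(frame, candidate_terms, nm_maxfev=nm_maxfev)
    theta0 = (math.log(full.re_sd["bird"]), math.log(full.re_sd["month"]))
    fits = [full]
    for r in range(len(candidate_terms), -1, -1):
        for subset in itertools.combinations(candidate_terms, r):
            if subset == candidate_terms:
                continue
            try:
                fits.append(fit_mixed_logistic(
                    frame, subset, theta0=theta0,
                    nm_maxfev=nm_maxfev if nm_maxfev is not None else 60))
            except FitError:
                logger.warning("dredge: fit failed for terms %s; excluded", subset)
    fits.sort(key=lambda f: f.aicc)
    best = fits[0].aicc
    rel = np.array([math.exp(-0.5 * (f.aicc - best)) for f in fits])
    weights = rel / rel.sum()
    for f, d, wgt in zip(fits, (f.aicc - best for f in fits), weights):
        f.delta_aicc = float(d)
        f.weight = float(wgt)
    return fits


def ranking_table(fits: list[ModelFit]) -> pd.DataFrame:
    rows = [(" + ".join(f.terms) if f.terms else "(null)",
             f.aicc, f.delta_aicc, f.weight, f.loglik, f.k) for f in fits]
    return pd.DataFrame(rows, columns=["terms", "AICc", "dAICc", "weight",
                                       "logLik", "k"])


def average_models(fits: list[ModelFit],
                   weight_floor: float = WEIGHT_FLOOR) -> pd.DataFrame:
    """Full (zero-substitution) averaging over models with weight >= floor.

    Weights renormalize over the retained set.  A coefficient absent from a
    model contributes 0 with zero conditional variance; the adjusted SE is
    sqrt(sum_i w_i (SE_i^2 + (b_i - b_bar)^2)).  Returns per-coefficient
    estimate, adjusted SE, z, and two-sided p, ordered by |z| descending.
    """
    kept = [f for f in fits if np.isfinite(f.weight) and f.weight >= weight_floor]
    if not kept:
        raise ValueError("no model at or above the weight floor")
    w = np.array([f.weight for f in kept])
    w = w / w.sum()
    names: list[str] = []
    for f in kept:
        names.extend(c for c in f.coef.index if c not in names)
    rows = []
    for name in names:
        b = np.array([f.coef.get(name, 0.0) for f in kept])
        s = np.array([f.se.get(name, 0.0) for f in kept])
        bbar = float(w @ b)
        var = float(w @ (s ** 2 + (b - bbar) ** 2))
        adj = math.sqrt(max(var, 0.0))
        z = bbar / adj if adj > 0 else 0.0
        p = 2.0 * float(norm.sf(abs(z)))
        rows.append((name, bbar, adj, z, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "estimate", "adj_se", "z", "p"])
    return out.reindex(out["z"].abs().sort_values(ascending=False).index)\
              .reset_index(drop=True)


@dataclass
class HabitatResult:
    contrast: str
    fits: list
    ranking: pd.DataFrame
    averaged: pd.DataFrame
    top: ModelFit
    params: dict = field(default_factory=dict)


def run_habitat_models(frames: dict[str, pd.DataFrame],
                       candidate_terms: tuple[str, ...] = CANDIDATE_TERMS,
                       weight_floor: float = WEIGHT_FLOOR,
                       nm_maxfev: int | None = None) -> dict[str, HabitatResult]:
    """Dredge and average each contrast's frame."""
    out = {}
    for name, frame in frames.items():
        fits = dredge_aicc(frame, candidate_terms, nm_maxfev=nm_maxfev)
        out[name] = HabitatResult(
            contrast=name, fits=fits, ranking=ranking_table(fits),
            averaged=average_models(fits, weight_floor=weight_floor),
            top=fits[0],
            params={"weight_floor": weight_floor,
                    "candidate_terms": candidate_terms})
    return out
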