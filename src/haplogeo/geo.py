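"""Geographic distances, the isolation-by-distance (IBD) regression, the
Mantel permutation test, and diversity-elevation correlation.

IBD is assessed with the linearised-Fst regression
``Fst/(1-Fst) = a + b * ln(km)`` over unordered population pairs; a slope b
significantly above zero indicates differentiation increasing with
distance.  Because pair observations are not independent, the OLS slope
p-value is reported alongside a Mantel permutation p on the same
transformed matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .structure import DistanceMatrix

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km between two (lon, lat) points in degrees."""
    lam1, phi1, lam2, phi2 = map(math.radians, (lon1, lat1, lon2, lat2))
    a = (
        math.sin((phi2 - phi1) / 2) ** 2
        + math.cos(phi1) * math.cos(phi2) * math.sin((lam2 - lam1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def population_coordinates(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-population mean longitude/latitude/elevation."""
    return samples.groupby("population", sort=False)[
        ["longitude", "latitude", "elevation"]
    ].mean()


def geographic_distance_matrix(samples: pd.DataFrame) -> DistanceMatrix:
    """Pairwise great-circle distances (km) between population centroids."""
    coords = population_coordinates(samples)
    pops = list(coords.index)
    k = len(pops)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = haversine_km(
                coords.iloc[i, 0], coords.iloc[i, 1], coords.iloc[j, 0], coords.iloc[j, 1]
            )
    return DistanceMatrix(tuple(pops), d)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class IbdFit:
    intercept: float
    slope: float
    r_squared: float
    p_slope: float
    p_mantel: float
    n_pairs: int
    n_excluded: int


def mantel_test(
    m1: DistanceMatrix,
    m2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "greater",
) -> CorrelationResult:
    """Mantel permutation test of matrix association.

    r is the Pearson correlation over off-diagonal pairs; the null permutes
    the row/column order of ``m2`` jointly.  p uses the
    (1 + #extreme)/(n_perm + 1) convention.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if m1.labels != m2.labels:
        m2 = m2.reorder(m1.labels)
    x = m1.condensed()
    k = len(m1.labels)
    y_mat = m2.values
    y = m2.condensed()
    if np.std(x) == 0 or np.std(y) == 0:
        raise InsufficientDataError("constant matrix: Mantel r undefined")
    r_obs = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(k, k=1)
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        yp = y_mat[np.ix_(perm, perm)][iu]
        rp = float(stats.pearsonr(x, yp)[0])
        if alternative == "greater":
            hit = rp >= r_obs - 1e-12
        elif alternative == "less":
            hit = rp <= r_obs + 1e-12
        else:
            hit = abs(rp) >= abs(r_obs) - 1e-12
        extreme += hit
    return CorrelationResult(r_obs, (extreme + 1) / (n_perm + 1), len(x))


def ibd_regression(
    pairwise_fst: DistanceMatrix,
    pairwise_km: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    clamp_negative_fst: bool = True,
) -> IbdFit:
    """OLS of Fst/(1-Fst) on ln(km) over unordered population pairs.

    Pairs with Fst >= 1, NaN Fst, or zero distance are excluded (counted in
    ``n_excluded``).  Negative Fst estimates are clamped to 0 before the
    transform by default, keeping it monotone and finite.
    """
    if pairwise_fst.labels != pairwise_km.labels:
        pairwise_km = pairwise_km.reorder(pairwise_fst.labels)
    fst = pairwise_fst.condensed().copy()
    km = pairwise_km.condensed()
    if clamp_negative_fst:
        fst = np.maximum(fst, 0.0)
    usable = np.isfinite(fst) & (fst < 1.0) & (km > 0.0)
    n_excl = int((~usable).sum())
    fst, km = fst[usable], km[usable]
    if len(fst) < 3:
        raise InsufficientDataError("fewer than 3 usable pairs for IBD regression")
    y = fst / (1.0 - fst)
    x = np.log(km)
    fit = stats.linregress(x, y)
    # Mantel on the transformed matrices restricted to usable pairs is not a
    # proper matrix permutation; run it on the full transformed matrices.
    k = len(pairwise_fst.labels)
    iu = np.triu_indices(k, k=1)
    fmat = np.zeros((k, k))
    f_full = pairwise_fst.condensed().copy()
    if clamp_negative_fst:
        f_full = np.maximum(f_full, 0.0)
    f_full = np.where(np.isfinite(f_full) & (f_full < 1.0), f_full, 0.0)
    fmat[iu] = f_full / (1.0 - f_full)
    fmat += fmat.T
    gmat = np.zeros((k, k))
    gkm = np.maximum(pairwise_km.condensed(), 1e-9)
    gmat[iu] = np.log(gkm)
    gmat += gmat.T
    try:
        mantel = mantel_test(
            DistanceMatrix(pairwise_fst.labels, fmat),
            DistanceMatrix(pairwise_fst.labels, gmat),
            n_perm=n_perm,
            seed=seed,
        )
    except InsufficientDataError:  # constant matrix: OLS fit still reported
        mantel = CorrelationResult(float("nan"), float("nan"), len(x))
    return IbdFit(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        p_slope=float(fit.pvalue),
        p_mantel=mantel.p_value,
        n_pairs=int(len(fst)),
        n_excluded=n_excl,
    )


def diversity_elevation_correlation(h_values, elevations) -> CorrelationResult:
    """Pearson correlation of per-population diversity with elevation."""
    h = np.asarray(list(h_values), dtype=float)
    e = np.asarray(list(elevations), dtype=float)
    if len(h) != len(e):
        raise ValueError("mismatched lengths")
    if len(h) < 3:
        raise InsufficientDataError("need >= 3 populations for a correlation")
    if np.std(h) == 0 or np.std(e) == 0:
        raise InsufficientDataError("zero variance: correlation undefined")
    r, p = stats.pearsonr(h, e)
    return CorrelationResult(float(r), float(p), len(h))


def ibd_pairs_frame(
    pairwise_fst: DistanceMatrix, pairwise_km: DistanceMatrix, clamp_negative_fst: bool = True
) -> pd.DataFrame:
    """Long-form pair table (pop1, pop2, km, fst, fst/(1-fst))."""
    labels = pairwise_fst.labels
    km = pairwise_km.reorder(labels)
    rows = []
    for i, p1 in enumerate(labels):
        for j in range(i + 1, len(labels)):
            f = pairwise_fst.values[i, j]
            fc = max(f, 0.0) if clamp_negative_fst and np.isfinite(f) else f
            t = fc / (1.0 - fc) if np.isfinite(fc) and fc < 1.0 else np.nan
            rows.append((p1, labels[j], km.values[i, j], f, t))
    return pd.DataFrame(rows, columns=["pop1", "pop2", "km", "fst", "fst_transformed"])
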