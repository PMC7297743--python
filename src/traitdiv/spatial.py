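"""Geodesic distances and Moran's I spatial-autocorrelation correlogram.

Distances use Vincenty's inverse method on the WGS84 ellipsoid (a = 6378137 m,
f = 1/298.257223563), iterated to 1e-12. Moran's I is computed with binary
distance-class membership weights (row-unstandardized); per-class two-sided
p-values come from permuting the values over locations, with the +1
small-sample correction. Under the null the expectation of I is -1/(n-1).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd

_WGS84_A = 6378137.0
_WGS84_F = 1 / 298.257223563
_WGS84_B = _WGS84_A * (1 - _WGS84_F)


def vincenty_distance(a: tuple[float, float], b: tuple[float, float],
                      tol: float = 1e-12, max_iter: int = 1000) -> float:
    """WGS84 inverse geodesic distance in km between (lat, lon) points in degrees.

    Near-antipodal pairs for which the iteration does not converge fall back to
    the great-circle (haversine) distance on the mean-radius sphere, with a
    warning; the error of that fallback is below 0.6%.
    """
    lat1, lon1 = a
    lat2, lon2 = b
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (abs(lat) <= 90 and abs(lon) <= 180):
            raise ValueError(f"invalid coordinate ({lat}, {lon})")
    if a == b:
        return 0.0
    u1 = math.atan((1 - _WGS84_F) * math.tan(math.radians(lat1)))
    u2 = math.atan((1 - _WGS84_F) * math.tan(math.radians(lat2)))
    ell = math.radians(lon2 - lon1)
    s_u1, c_u1, s_u2, c_u2 = math.sin(u1), math.cos(u1), math.sin(u2), math.cos(u2)
    lam = ell
    converged = False
    for _ in range(max_iter):
        s_lam, c_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(c_u2 * s_lam, c_u1 * s_u2 - s_u1 * c_u2 * c_lam)
        if sin_sigma == 0:
            return 0.0  # coincident points
        cos_sigma = s_u1 * s_u2 + c_u1 * c_u2 * c_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = c_u1 * c_u2 * s_lam / sin_sigma
        cos2_alpha = 1 - sin_alpha ** 2
        cos_2sm = cos_sigma - 2 * s_u1 * s_u2 / cos2_alpha if cos2_alpha else 0.0
        c = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_new = ell + (1 - c) * _WGS84_F * sin_alpha * (
            sigma + c * sin_sigma * (cos_2sm + c * cos_sigma * (-1 + 2 * cos_2sm ** 2)))
        if abs(lam_new - lam) < tol:
            lam = lam_new
            converged = True
            break
        lam = lam_new
    if not converged:
        warnings.warn("Vincenty iteration did not converge (near-antipodal pair); "
                      "falling back to great-circle distance")
        return _haversine(lat1, lon1, lat2, lon2)
    u_sq = cos2_alpha * (_WGS84_A ** 2 - _WGS84_B ** 2) / _WGS84_B ** 2
    big_a = 1 + u_sq / 16384 * (4096 + u_sq * (-768 + u_sq * (320 - 175 * u_sq)))
    big_b = u_sq / 1024 * (256 + u_sq * (-128 + u_sq * (74 - 47 * u_sq)))
    d_sigma = big_b * sin_sigma * (
        cos_2sm + big_b / 4 * (cos_sigma * (-1 + 2 * cos_2sm ** 2)
                               - big_b / 6 * cos_2sm * (-3 + 4 * sin_sigma ** 2)
                               * (-3 + 4 * cos_2sm ** 2)))
    return _WGS84_B * big_a * (sigma - d_sigma) / 1000.0


def _haversine(lat1, lon1, lat2, lon2, radius_km: float = 6371.0088) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    h = math.sin((p2 - p1) / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * radius_km * math.asin(math.sqrt(h))


def pairwise_distance_matrix(locs: pd.DataFrame, axis_order: str = "latlon") -> pd.DataFrame:
    """Square geodesic distance matrix (km) over a location table.

    ``axis_order='lonlat'`` evaluates the geodesic with latitude and longitude
    interchanged. That is never geographically meaningful; it exists to
    reproduce published distance summaries computed by feeding (lat, lon)
    columns to software expecting (lon, lat).
    """
    ids = locs["location_id"].tolist()
    lat, lon = locs["latitude"].to_numpy(), locs["longitude"].to_numpy()
    if axis_order == "lonlat":
        lat, lon = lon, lat
    elif axis_order != "latlon":
        raise ValueError("axis_order must be 'latlon' or 'lonlat'")
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = vincenty_distance((lat[i], lon[i]), (lat[j], lon[j]))
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def pairwise_distance_summary(locs: pd.DataFrame, exclude: str | None = None,
                              axis_order: str = "latlon",
                              ) -> tuple[float, float, pd.DataFrame]:
    """Mean and sample SD of geodesic distance over all unordered location pairs.

    ``exclude`` drops one location (e.g. a geographic outlier) before
    summarizing. With a single pair the SD is reported as 0.
    """
    if exclude is not None:
        locs = locs[locs["location_id"] != exclude]
    if len(locs) < 2:
        raise ValueError("need at least 2 locations")
    mat = pairwise_distance_matrix(locs, axis_order=axis_order)
    vals = mat.to_numpy()[np.triu_indices(len(mat), k=1)]
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd, mat


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

def morans_i(values: pd.Series, weights: np.ndarray) -> float:
    """Moran's I = (n/W) * sum_ij w_ij z_i z_j / sum_i z_i^2 with centered values."""
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 3:
        raise ValueError("Moran's I needs at least 3 locations")
    w = np.asarray(weights, dtype=float)
    np.fill_diagonal(w, 0.0)
    total_w = w.sum()
    if total_w == 0:
        raise ValueError("empty weight matrix (no pairs in class)")
    z = z - z.mean()
    denom = (z ** 2).sum()
    if denom == 0:
        raise ValueError("Moran's I undefined for constant values")
    return float(n / total_w * (z[:, None] * z[None, :] * w).sum() / denom)


def correlogram(residuals: pd.Series, locs: pd.DataFrame, increment_km: float,
                resamples: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Moran's I per distance class with two-sided permutation p-values.

    Distance classes are equal-width bins of ``increment_km`` covering
    (0, max distance]; class weights are binary pair membership. For each class
    the residuals are permuted over locations ``resamples`` times and the
    two-sided p is 2*min(P(I* >= I), P(I* <= I)) with the +1 correction, capped
    at 1. Classes with no pairs are reported with NaN. The returned frame's
    ``attrs['significant_share']`` is the fraction of defined classes with
    p < .05.
    """
    if increment_km <= 0:
        raise ValueError("increment_km must be positive")
    resid = residuals.loc[locs["location_id"]].to_numpy(dtype=float)
    mat = pairwise_distance_matrix(locs).to_numpy()
    n = len(resid)
    rng = np.random.default_rng(seed)
    n_classes = max(int(np.ceil(mat.max() / increment_km)), 1)
    perms = np.array([rng.permutation(resid) for _ in range(resamples)])
    rows = []
    for k in range(n_classes):
        lo, hi = k * increment_km, (k + 1) * increment_km
        w = ((mat > lo) & (mat <= hi)).astype(float)
        n_pairs = int(w.sum() // 2)
        if n_pairs == 0:
            rows.append({"class_lo_km": lo, "class_hi_km": hi, "n_pairs": 0,
                         "morans_i": np.nan, "p": np.nan,
                         "resamples": resamples, "seed": seed})
            continue
        obs = morans_i(pd.Series(resid), w)
        null = np.array([morans_i(pd.Series(perms[r]), w) for r in range(resamples)])
        p_hi = (np.sum(null >= obs) + 1) / (resamples + 1)
        p_lo = (np.sum(null <= obs) + 1) / (resamples + 1)
        rows.append({"class_lo_km": lo, "class_hi_km": hi, "n_pairs": n_pairs,
                     "morans_i": obs, "p": min(2 * min(p_hi, p_lo), 1.0),
                     "resamples": resamples, "seed": seed})
    out = pd.DataFrame(rows)
    defined = out["p"].dropna()
    out.attrs["significant_share"] = float((defined < 0.05).mean()) if len(defined) else np.nan
    return out
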