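"""Forecast evaluation and occurrence-geometry utilities.

Spatial thinning (rarefaction to a minimum great-circle distance), background
radii from mean pairwise distances, omission-rate thresholds, confusion
metrics (sensitivity, specificity, TSS), the partial-ROC AUC ratio with its
bootstrap significance, and the Mobility-Oriented Parity (MOP) extrapolation
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvalResult",
    "haversine_km",
    "thin_occurrences",
    "background_radius",
    "omission_threshold",
    "confusion_metrics",
    "partial_roc",
    "mop_mask",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088
DEFAULT_THINNING_KM = 50.0
INVASIVE_FALLBACK_THINNING_KM = 10.0


@dataclass
class EvalResult:
    sensitivity: float
    specificity: float
    tss: float
    auc_ratio: float = float("nan")
    p_value: float = float("nan")
    threshold: float = float("nan")
    omission_rate: float = float("nan")


def haversine_km(p1, p2) -> float:
    """Great-circle distance between (lon, lat) points in km."""
    lon1, lat1 = np.radians(np.asarray(p1, dtype=float))
    lon2, lat2 = np.radians(np.asarray(p2, dtype=float))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def _pairwise_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    lon_r, lat_r = np.radians(lon), np.radians(lat)
    dlat = lat_r[:, None] - lat_r[None, :]
    dlon = lon_r[:, None] - lon_r[None, :]
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat_r[:, None]) * np.cos(lat_r[None, :]) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def thin_occurrences(points: pd.DataFrame, min_km: float = DEFAULT_THINNING_KM, seed: int = 0) -> pd.DataFrame:
    """Greedy spatial rarefaction: keep points >= ``min_km`` apart.

    Points are visited in a seeded random order; a point is retained iff it
    lies at least ``min_km`` from every point already kept, so the retained
    set (but not its size guarantee) depends on the order — hence the seed.
    """
    if min_km <= 0:
        raise ValueError("min_km must be positive")
    if len(points) == 0:
        return points.copy()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(points))
    lon = points["lon"].to_numpy()[order]
    lat = points["lat"].to_numpy()[order]
    kept: list[int] = []
    for i in range(len(points)):
        ok = True
        for j in kept:
            if haversine_km((lon[j], lat[j]), (lon[i], lat[i])) < min_km:
                ok = False
                break
        if ok:
            kept.append(i)
    return points.iloc[np.sort(order[kept])].reset_index(drop=True)


def background_radius(points: pd.DataFrame) -> float:
    """Mean pairwise great-circle distance between occurrences [km]."""
    if len(points) < 2:
        raise ValueError("at least two points required")
    d = _pairwise_km(points["lon"].to_numpy(), points["lat"].to_numpy())
    iu = np.triu_indices(len(points), k=1)
    return float(d[iu].mean())


def omission_threshold(scores_at_presences, rate: float = 0.05) -> float:
    """Suitability threshold admitting at most ``rate`` training omission.

    Uses the lower-interpolation quantile of the presence scores, so no more
    than ``rate`` of training presences score strictly below the threshold.
    """
    scores = np.asarray(scores_at_presences, dtype=float)
    if scores.size == 0:
        raise ValueError("no presence scores")
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    return float(np.quantile(scores, rate, method="lower"))


def confusion_metrics(pred_at_risk, is_presence) -> EvalResult:
    """Sensitivity, specificity and TSS from binary predictions and labels."""
    pred = np.asarray(pred_at_risk, dtype=bool)
    lab = np.asarray(is_presence, dtype=bool)
    if lab.all() or not lab.any():
        raise ValueError("both presences and background required")
    sens = float(pred[lab].mean())
    spec = float((~pred[~lab]).mean())
    return EvalResult(sensitivity=sens, specificity=spec, tss=sens + spec - 1.0)


def partial_roc(
    scores_surface,
    presence_scores,
    e_rate: float = 0.05,
    iterations: int = 1000,
    seed: int = 0,
    bootstrap_fraction: float = 0.5,
) -> tuple[float, float]:
    """Partial-ROC AUC ratio restricted to omission <= ``e_rate``.

    The curve plots the fraction of test presences scoring at or above a
    threshold (sensitivity) against the fraction of the score surface doing
    so (proportion of area predicted present).  Both partial areas — model
    curve and the diagonal null — are integrated over the thresholds with
    sensitivity >= 1 - e_rate; their ratio is the statistic.  Each bootstrap
    iteration resamples half of the presences with replacement; the reported
    ratio is the bootstrap mean and the p-value the fraction of iterations
    with ratio <= 1.
    """
    surface = np.asarray(scores_surface, dtype=float).ravel()
    pres = np.asarray(presence_scores, dtype=float).ravel()
    if pres.size < 10:
        raise ValueError("at least 10 test presences required")
    if np.ptp(surface) == 0:
        raise ValueError("degenerate (constant) score surface")
    thresholds = np.unique(np.quantile(surface, np.linspace(0.0, 1.0, 101)))
    # fraction of cells / presences at or above each threshold
    area = 1.0 - np.searchsorted(np.sort(surface), thresholds, side="left") / surface.size

    def ratio(sample: np.ndarray) -> float:
        sens = 1.0 - np.searchsorted(np.sort(sample), thresholds, side="left") / sample.size
        keep = sens >= 1.0 - e_rate
        if keep.sum() < 2:
            return np.nan
        x = area[keep]
        y = sens[keep]
        order = np.argsort(x)
        x, y = x[order], y[order]
        if np.ptp(x) == 0:
            return np.nan
        auc_model = np.trapezoid(y, x)
        auc_null = np.trapezoid(x, x)
        return auc_model / auc_null if auc_null > 0 else np.nan

    rng = np.random.default_rng(seed)
    k = max(1, int(round(bootstrap_fraction * pres.size)))
    ratios = np.empty(iterations)
    for i in range(iterations):
        ratios[i] = ratio(pres[rng.integers(0, pres.size, size=k)])
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size == 0:
        return float("nan"), float("nan")
    return float(ratios.mean()), float(np.mean(ratios <= 1.0))


def mop_mask(
    calibration: np.ndarray,
    projection: np.ndarray,
    reference_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Mobility-Oriented Parity: environmental similarity and strict extrapolation.

    Variables are normalized by the calibration range.  For each projection
    point the mean Euclidean distance to its nearest ``reference_fraction``
    of calibration points is computed; similarity is ``1 - d / d_max`` with
    ``d_max`` the largest such distance over the projection set.  A point is
    in strict extrapolation when any variable leaves the calibration
    min-max.  Returns (similarity, strict_extrapolation).
    """
    cal = np.atleast_2d(np.asarray(calibration, dtype=float))
    proj = np.atleast_2d(np.asarray(projection, dtype=float))
    if cal.shape[1] != proj.shape[1]:
        raise ValueError("calibration and projection variables differ")
    lo, hi = cal.min(axis=0), cal.max(axis=0)
    strict = np.any((proj < lo) | (proj > hi), axis=1)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    cal_n = (cal - lo) / span
    proj_n = (proj - lo) / span
    k = max(1, int(np.ceil(reference_fraction * cal.shape[0])))
    mean_d = np.empty(proj.shape[0])
    chunk = max(1, int(2e7 // max(cal.shape[0], 1)))
    for start in range(0, proj.shape[0], chunk):
        block = proj_n[start : start + chunk]
        d = np.sqrt(((block[:, None, :] - cal_n[None, :, :]) ** 2).sum(axis=2))
        part = np.partition(d, k - 1, axis=1)[:, :k]
        mean_d[start : start + chunk] = part.mean(axis=1)
    dmax = mean_d.max()
    similarity = 1.0 - (mean_d / dmax if dmax > 0 else mean_d)
    return similarity, strict
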