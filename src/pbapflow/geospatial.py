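"""Great-circle geometry, distance-to-land and pristine-marine segregation.

A ship-borne aerosol record is called *pristine-marine* when it was collected
strictly farther than a threshold distance (default 200 km) from any coastline,
and *terrestrially influenced* otherwise.  The threshold itself can be chosen
objectively by scanning candidate thresholds and locating the distance beyond
which the correlation between fluorescent-particle concentration and a sea-spray
proxy (e.g. wind speed) stops changing — the correlation "plateau".

Coastlines are represented as densified vertex point clouds (vertex spacing
<= 10 km), so distance to land reduces to a minimum over great-circle
point distances; at the 200-km scales of interest the densification error
is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

PRISTINE = "pristine_marine"
TERRESTRIAL = "terrestrial"

__all__ = [
    "EARTH_RADIUS_KM",
    "PRISTINE",
    "TERRESTRIAL",
    "haversine_km",
    "distance_to_land",
    "segregate",
    "ThresholdScan",
    "scan_distance_threshold",
]


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Vectorised over numpy broadcasting rules.  Raises ``ValueError`` for
    latitudes outside [-90, 90].
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90.0) or np.any(np.abs(lat2) > 90.0):
        raise ValueError("latitude outside [-90, 90] degrees")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_to_land(track: pd.DataFrame, coastline: np.ndarray) -> np.ndarray:
    """Minimum great-circle distance (km) from each track point to the coastline.

    Parameters
    ----------
    track : DataFrame with ``lat``/``lon`` columns (degrees).
    coastline : (n, 2) array of (lat, lon) vertices, densified to <= 10 km
        spacing.  An empty coastline means open ocean: all distances are +inf.
    """
    coastline = np.asarray(coastline, dtype=float).reshape(-1, 2)
    lat = track["lat"].to_numpy(dtype=float)
    lon = track["lon"].to_numpy(dtype=float)
    if coastline.shape[0] == 0:
        return np.full(lat.shape, np.inf)
    # chunk over track points to bound the (n_track, n_vertex) broadcast
    out = np.empty(lat.shape, dtype=float)
    step = max(1, int(2_000_000 / max(1, coastline.shape[0])))
    for i in range(0, lat.size, step):
        sl = slice(i, i + step)
        d = haversine_km(
            lat[sl, None], lon[sl, None], coastline[None, :, 0], coastline[None, :, 1]
        )
        out[sl] = d.min(axis=1)
    return out


def segregate(track: pd.DataFrame, coastline: np.ndarray, threshold_km: float = 200.0) -> pd.DataFrame:
    """Classify each track point as pristine-marine or terrestrially influenced.

    A point is pristine-marine iff its distance to land is *strictly* greater
    than ``threshold_km`` (ties count as terrestrial).  Returns a copy of the
    track with ``distance_to_land_km`` and ``category`` columns added.
    """
    out = track.copy()
    d = distance_to_land(track, coastline)
    out["distance_to_land_km"] = d
    out["category"] = np.where(d > threshold_km, PRISTINE, TERRESTRIAL)
    return out


@dataclass
class ThresholdScan:
    """Correlation-vs-distance-threshold scan result.

    ``r`` is NaN where the pristine subset at that threshold had fewer than
    ``min_pairs`` valid pairs; those thresholds are excluded from the plateau
    search.  ``plateau_km`` is the smallest threshold t* such that
    |R(t*) - R(t)| < eps for every larger (valid) threshold t.
    """

    thresholds_km: np.ndarray
    r: np.ndarray
    n_pairs: np.ndarray
    eps: float
    plateau_km: float = field(init=False)

    def __post_init__(self) -> None:
        valid = np.isfinite(self.r)
        if not valid.any():
            raise ValueError("no threshold left a pristine subset with enough pairs")
        self.plateau_km = float("nan")
        idx = np.flatnonzero(valid)
        for k, i in enumerate(idx):
            later = idx[k + 1:]
            if np.all(np.abs(self.r[later] - self.r[i]) < self.eps):
                self.plateau_km = float(self.thresholds_km[i])
                break


def scan_distance_threshold(
    fluor_series,
    proxy_series,
    distances_km,
    thresholds_km,
    eps: float = 0.02,
    min_pairs: int = 25,
) -> ThresholdScan:
    """Scan segregation thresholds and estimate the correlation plateau.

    For each candidate threshold, Pearson R is computed between the fluorescent
    concentration series and the proxy series over the subset with
    ``distance > threshold``.  All three series must be index-aligned
    (e.g. hourly).  Non-finite samples are dropped pairwise.
    """
    from .stats import pearson_r

    x = np.asarray(fluor_series, dtype=float)
    y = np.asarray(proxy_series, dtype=float)
    d = np.asarray(distances_km, dtype=float)
    if not (x.shape == y.shape == d.shape):
        raise ValueError("fluor, proxy and distance series must be aligned")
    thresholds_km = np.sort(np.asarray(thresholds_km, dtype=float))
    if thresholds_km.size < 2:
        raise ValueError("need at least 2 candidate thresholds")
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(d)
    r = np.full(thresholds_km.shape, np.nan)
    n = np.zeros(thresholds_km.shape, dtype=int)
    for i, t in enumerate(thresholds_km):
        sel = ok & (d > t)
        n[i] = int(sel.sum())
        if n[i] >= min_pairs:
            r[i] = pearson_r(x[sel], y[sel])
    return ThresholdScan(thresholds_km=thresholds_km, r=r, n_pairs=n, eps=eps)
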