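"""End-to-end parameter-recovery runs on the calibrated synthetic presets.

These helpers exercise the whole chain — campaign generation, forced-trigger
threshold estimation, tier classification, hourly aggregation, pristine-marine
segregation, threshold scanning — and report the recovered campaign
statistics.  They are used both by the acceptance tests and by the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import geospatial
from .aggregation import time_binned_series
from .fluorescence import classify_particles, compute_ft_stats
from .synthetic_data import generate_campaign, get_preset

__all__ = ["pristine_recovery", "plateau_recovery"]


def _hourly_products(campaign):
    thresholds = compute_ft_stats(campaign.ft_records)
    lab3 = classify_particles(campaign.particles, thresholds, 3)
    lab9 = classify_particles(campaign.particles, thresholds, 9)
    hourly = time_binned_series(
        campaign.particles,
        lab3["in_tier"].to_numpy(),
        lab9["in_tier"].to_numpy(),
        bin_width="1h",
        flow_l_min=campaign.preset.sample_flow_l_min,
    )
    d = geospatial.distance_to_land(campaign.track, campaign.coastline)
    dist = (
        campaign.track.assign(_d=d)
        .set_index("timestamp")["_d"]
        .resample("1h")
        .min()
        .reindex(hourly.index)
    )
    return hourly, dist


def pristine_recovery(seed=None, threshold_km: float = 200.0, **overrides) -> dict:
    """Full-pipeline recovery of the pristine-marine campaign medians.

    Generates the default ``pristine`` preset (90 days), classifies at 3σ/9σ,
    aggregates hourly coarse concentrations and fractions, restricts to
    pristine-marine hours (> ``threshold_km`` from land) and reports medians.
    """
    campaign = generate_campaign(get_preset("pristine", **overrides), seed=seed)
    hourly, dist = _hourly_products(campaign)
    pristine = hourly[dist.to_numpy() > threshold_km]
    return {
        "n_hours": int(len(pristine)),
        "median_conc_fluor_per_l": float(pristine["conc_fluor"].median()),
        "median_conc_hyper_per_l": float(pristine["conc_hyper"].median()),
        "median_frac_fluor_pct": float(100.0 * pristine["frac_fluor"].median()),
        "median_frac_hyper_pct": float(100.0 * pristine["frac_hyper"].median()),
    }


def plateau_recovery(
    seed=None,
    thresholds_km=None,
    eps: float = 0.02,
    proxy: str = "u10n",
    **overrides,
) -> dict:
    """Distance-threshold scan on the coastal ``mixed`` preset.

    Computes Pearson R between hourly fluorescent concentration and wind speed
    over the pristine subset at each candidate threshold (25–500 km by
    default) and reports the plateau estimate.
    """
    if thresholds_km is None:
        thresholds_km = np.arange(25.0, 501.0, 25.0)
    campaign = generate_campaign(get_preset("mixed", **overrides), seed=seed)
    hourly, dist = _hourly_products(campaign)
    wind = (
        campaign.track.set_index("timestamp")[proxy].resample("1h").mean().reindex(hourly.index)
    )
    scan = geospatial.scan_distance_threshold(
        hourly["conc_fluor"], wind, dist, thresholds_km, eps=eps
    )
    return {
        "plateau_km": float(scan.plateau_km),
        "n_hours": int(len(hourly)),
        "thresholds_km": scan.thresholds_km,
        "r": scan.r,
    }
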