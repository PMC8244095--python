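"""Synthetic WIBS-style campaign generator with known ground truth.

Emulates the statistical structure of a ship-borne single-particle fluorescence
data set over a remote ocean so that the full analysis pipeline (thresholding,
ABC classification, aggregation, segregation, correlation) can be exercised and
validated without access to campaign raw data:

* a wind-modulated coarse sea-spray particle stream (lognormal optical sizes,
  homogeneous Poisson arrivals within 5-min bins at rate concentration ×
  sample flow);
* a small fluorescent subpopulation (default 1.6% of coarse particles) with a
  hyper-fluorescent subset (default 0.13%), whose detection probability rises
  with optical diameter and whose hyper size distribution has a coarse mode
  near 5–8 µm;
* slowly varying "biological" modulation of the fluorescent fractions, to
  which synthetic seawater variables (bacteria- and phytoplankton-like) are
  coupled through a Gaussian copula with configurable rank correlation;
* an optional terrestrial plume source whose emission rate decays as
  exp(-d/L) with distance d to a scenario coastline;
* forced-trigger background records (Gaussian truncated at zero) from which
  the 3σ/9σ thresholds are later re-derived by the pipeline.

Emitter amplitudes in each "lit" channel are drawn from lognormals truncated
to the tier's own threshold band, so a particle's detected tier coincides with
its ground-truth tier; the fraction-vs-size curves are rescaled numerically at
preset build time so the expected detected fractions among coarse particles
equal ``fluor_fraction`` and ``hyper_fraction`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .fluorescence import FLAG_CONTAMINATED
from .geospatial import EARTH_RADIUS_KM, haversine_km

CAMPAIGN_START = pd.Timestamp("2017-01-06T00:00:00")

#: ground-truth population codes
POP_SSA_BACKGROUND = 0
POP_BACTERIA_LIKE = 1
POP_PHYTOPLANKTON_LIKE = 2
POP_TERRESTRIAL = 3
POPULATION_NAMES = ("ssa_background", "bacteria_like", "phytoplankton_like", "terrestrial")

#: ground-truth tier codes
TIER_CODE_NONE, TIER_CODE_FLUOR, TIER_CODE_HYPER = 0, 1, 2

# ABC pattern codes (bit0=A, bit1=B, bit2=C) and per-population probabilities
_PATTERN_CODES = np.array([1, 2, 4, 3, 5, 6, 7])  # A B C AB AC BC ABC
_PATTERN_PROBS = {
    "marine_fluor": np.array([0.26, 0.33, 0.12, 0.14, 0.005, 0.045, 0.10]),
    "marine_hyper": np.array([0.28, 0.30, 0.03, 0.18, 0.005, 0.055, 0.15]),
    "terrestrial": np.array([0.15, 0.10, 0.15, 0.05, 0.01, 0.40, 0.14]),
}

__all__ = [
    "ScenarioPreset",
    "GroundTruth",
    "Campaign",
    "get_preset",
    "PRESET_NAMES",
    "generate_ft_records",
    "generate_coastline",
    "generate_campaign",
]


# ---------------------------------------------------------------------------
# marine seawater variable coupling table: (category, signal, rho, median, sigma)

_MARINE_VARIABLES = [
    # name, category, latent signal, rank corr, median, lognormal sigma
    ("HDNA", "microbe_count", "fluor", 0.50, 5.0e5, 0.5),
    ("LDNA", "microbe_count", "fluor", 0.45, 3.0e5, 0.5),
    ("total_bacteria", "microbe_count", "fluor", 0.50, 8.0e5, 0.5),
    ("picoeukaryotes", "microbe_count", "fluor", 0.45, 5.0e3, 0.6),
    ("Pras3", "taxa_mass", "hyper", 0.69, 0.05, 0.7),
    ("Chloro", "taxa_mass", "hyper", 0.55, 0.08, 0.7),
    ("Pelago", "taxa_mass", "hyper", 0.44, 0.06, 0.7),
    ("TEP", "OM", "fluor", 0.20, 50.0, 0.5),
    ("CSP", "OM", "fluor", 0.15, 40.0, 0.5),
    ("CDOM", "OM", "hyper", 0.10, 0.5, 0.4),
]


@dataclass(frozen=True)
class ScenarioPreset:
    """Parameters defining one synthetic campaign scenario.

    ``base_coarse_conc`` is the target *median* coarse (> 1 µm) number
    concentration in L^-1; the default presets set it so the median detected
    fluorescent concentration lands on the campaign calibration value
    (11.4 L^-1 at a 1.6% fluorescent fraction).
    """

    name: str
    duration_h: float
    base_coarse_conc: float          # L^-1, median coarse (>1 um) concentration
    wind_coupling: float             # exponent linking wind speed to coarse conc
    fluor_fraction: float            # detected fluorescent fraction of coarse particles
    hyper_fraction: float            # detected hyper-fluorescent fraction of coarse
    hyper_size_mode_um: float        # centre of the hyper detection ramp (um)
    terrestrial_decay_km: float      # e-folding distance of the terrestrial source
    seed: int
    # instrument / sampling
    sample_flow_l_min: float = 0.23
    time_bin_min: float = 5.0
    ft_means: tuple = (50.0, 40.0, 30.0)
    ft_sds: tuple = (5.0, 4.0, 3.0)
    n_ft_records: int = 2000
    # size model (lognormal, truncated to size_range)
    size_median_um: float = 1.3
    size_sigma_log: float = 0.6
    size_range_um: tuple = (0.5, 16.0)
    # wind model (AR(1) on log wind speed)
    wind_median_ms: float = 9.0
    wind_sigma_log: float = 0.35
    wind_tau_h: float = 24.0
    conc_noise_log: float = 0.15
    # biological modulation of the fluorescent fractions (AR(1) on logs)
    frac_sigma_log: float = 0.35
    frac_tau_h: float = 24.0
    frac_signal_corr: float = 0.6
    # terrestrial source
    coastline_scenario: str = "none"
    terrestrial_coast_conc: float = 0.0   # L^-1 added at the coastline
    terrestrial_fluor_prob: float = 0.5
    terrestrial_hyper_prob: float = 0.05
    terrestrial_size_median_um: float = 2.0
    terrestrial_noise_log: float = 0.7    # plume intermittency (AR(1) on log)
    terrestrial_noise_tau_h: float = 6.0
    # coastal-excursion geometry of the meridian-coast track (km)
    dwell_min_km: float = 100.0
    dwell_max_km: float = 250.0
    # marine sampling
    marine_interval_h: float = 3.0
    # contamination injection (for quality-mask recovery tests)
    contaminated_time_fraction: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.hyper_fraction <= self.fluor_fraction <= 1.0):
            raise ValueError("require 0 <= hyper_fraction <= fluor_fraction <= 1")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.base_coarse_conc <= 0:
            raise ValueError("base_coarse_conc must be positive")


def _pristine() -> ScenarioPreset:
    # base concentration set so 1.6% of coarse particles gives the 11.4 L^-1
    # median fluorescent concentration
    return ScenarioPreset(
        name="pristine",
        duration_h=90 * 24.0,
        base_coarse_conc=11.4 / 0.016,
        wind_coupling=1.5,
        fluor_fraction=0.016,
        hyper_fraction=0.0013,
        hyper_size_mode_um=5.0,
        terrestrial_decay_km=60.0,
        seed=42,
        coastline_scenario="none",
        terrestrial_coast_conc=0.0,
    )


def _mixed() -> ScenarioPreset:
    # same marine stream, plus a coastal plume confined well inside 200 km
    return ScenarioPreset(
        name="mixed",
        duration_h=60 * 24.0,
        base_coarse_conc=11.4 / 0.016,
        wind_coupling=1.5,
        fluor_fraction=0.016,
        hyper_fraction=0.0013,
        hyper_size_mode_um=5.0,
        terrestrial_decay_km=70.0,
        seed=7,
        coastline_scenario="meridian-coast",
        terrestrial_coast_conc=250.0,
    )


_PRESET_FACTORIES = {"pristine": _pristine, "mixed": _mixed}
PRESET_NAMES = tuple(sorted(_PRESET_FACTORIES))


def get_preset(name: str, **overrides) -> ScenarioPreset:
    """Build a named preset, optionally overriding individual fields."""
    if name not in _PRESET_FACTORIES:
        raise KeyError(f"unknown preset {name!r}; known: {PRESET_NAMES}")
    p = _PRESET_FACTORIES[name]()
    return replace(p, **overrides) if overrides else p


# ---------------------------------------------------------------------------
# low-level samplers


def _trunc_lognormal(rng, n, median, sigma, lo=0.0, hi=np.inf):
    """Lognormal(ln median, sigma) truncated to (lo, hi), inverse-CDF sampled."""
    mu = np.log(median)
    a = ndtr((np.log(lo) - mu) / sigma) if lo > 0 else 0.0
    b = ndtr((np.log(hi) - mu) / sigma) if np.isfinite(hi) else 1.0
    u = rng.random(n)
    return np.exp(mu + sigma * ndtri(a + u * (b - a)))


def _ar1_log(rng, n_bins, sigma, tau_bins):
    """Stationary AR(1) series on the log scale, marginal N(0, sigma^2)."""
    phi = np.exp(-1.0 / max(tau_bins, 1e-9))
    innov_sd = sigma * np.sqrt(1.0 - phi**2)
    x = np.empty(n_bins)
    x[0] = rng.normal(0.0, sigma)
    eps = rng.normal(0.0, innov_sd, size=n_bins - 1) if n_bins > 1 else np.empty(0)
    for i in range(1, n_bins):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def generate_ft_records(n: int, channel_means, channel_sds, seed=None) -> pd.DataFrame:
    """Forced-trigger background records: per-channel Gaussian truncated at 0.

    At least two records are required (the sample SD is undefined otherwise);
    zero-SD channels yield constant records equal to the mean.
    """
    if n < 2:
        raise ValueError("need n >= 2 forced-trigger records (SD undefined)")
    means = np.asarray(channel_means, dtype=float)
    sds = np.asarray(channel_sds, dtype=float)
    if means.shape != (3,) or sds.shape != (3,):
        raise ValueError("channel_means and channel_sds must have 3 entries")
    if np.any(sds < 0):
        raise ValueError("channel SDs must be nonnegative")
    rng = np.random.default_rng(seed)
    cols = {}
    t0 = CAMPAIGN_START - pd.Timedelta(hours=1)
    cols["timestamp"] = t0 + pd.to_timedelta(np.arange(n), unit="s")
    for i, c in enumerate("abc"):
        if sds[i] == 0.0:
            cols[f"fl_{c}"] = np.full(n, means[i])
        else:
            a = -means[i] / sds[i]  # truncate at zero
            u = rng.random(n)
            lo = ndtr(a)
            cols[f"fl_{c}"] = means[i] + sds[i] * ndtri(lo + u * (1.0 - lo))
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# coastlines


def generate_coastline(scenario: str, **kw) -> np.ndarray:
    """Densified coastline vertex list (lat, lon), spacing <= 10 km.

    Scenarios: ``"none"`` (open ocean, empty list, all distances +inf),
    ``"island"`` (closed ring; kw: centre=(lat, lon), radius_km),
    ``"meridian-coast"`` (north-south line; kw: lon0, lat_range).
    """
    if scenario == "none":
        return np.empty((0, 2))
    if scenario == "island":
        clat, clon = kw.get("centre", (-50.0, 70.0))
        r = float(kw.get("radius_km", 30.0))
        n = max(8, int(np.ceil(2 * np.pi * r / 10.0)))
        theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        ang = r / EARTH_RADIUS_KM
        lat0, lon0 = np.radians(clat), np.radians(clon)
        lat = np.arcsin(
            np.sin(lat0) * np.cos(ang) + np.cos(lat0) * np.sin(ang) * np.cos(theta)
        )
        lon = lon0 + np.arctan2(
            np.sin(theta) * np.sin(ang) * np.cos(lat0),
            np.cos(ang) - np.sin(lat0) * np.sin(lat),
        )
        ring = np.column_stack([np.degrees(lat), np.degrees(lon)])
        return np.vstack([ring, ring[:1]])  # closed ring
    if scenario == "meridian-coast":
        lon0 = float(kw.get("lon0", 0.0))
        lat_lo, lat_hi = kw.get("lat_range", (-75.0, -35.0))
        step = 9.8 / 111.19  # < 10 km along a meridian
        lats = np.arange(lat_lo, lat_hi + step, step)
        return np.column_stack([lats, np.full(lats.shape, lon0)])
    raise KeyError(f"unknown coastline scenario {scenario!r}")


# ---------------------------------------------------------------------------
# fraction-vs-size ramps and their calibration


def _fluor_ramp(d, preset: ScenarioPreset):
    """Uncalibrated fluorescent detection probability vs optical diameter."""
    centre = max(preset.hyper_size_mode_um, 1.5) * 1.2
    return 0.013 + 0.39 * expit((np.log(d) - np.log(centre)) / 0.30)


def _hyper_ramp(d, preset: ScenarioPreset):
    """Uncalibrated hyper-fluorescent detection probability vs diameter."""
    return 0.0004 + 0.09 * expit((np.log(d) - np.log(preset.hyper_size_mode_um)) / 0.25)


def _coarse_mean(ramp_vals, d_grid, preset: ScenarioPreset):
    """Mean of a ramp over the coarse (>= 1 um) part of the size distribution."""
    mu, s = np.log(preset.size_median_um), preset.size_sigma_log
    ln_d = np.log(d_grid)
    pdf = np.exp(-0.5 * ((ln_d - mu) / s) ** 2)  # lognormal in d, uniform-in-ln grid
    w = pdf / pdf.sum()
    return float(np.sum(ramp_vals * w))


def _calibrate_scales(preset: ScenarioPreset):
    """Solve the deterministic ramp scales so the expected detected coarse
    fractions equal ``fluor_fraction`` and ``hyper_fraction``."""
    d = np.exp(np.linspace(np.log(1.0), np.log(preset.size_range_um[1]), 2001))
    mean_f = _coarse_mean(_fluor_ramp(d, preset), d, preset)
    mean_h = _coarse_mean(_hyper_ramp(d, preset), d, preset)
    c_f = preset.fluor_fraction / mean_f if mean_f > 0 else 0.0
    c_h = preset.hyper_fraction / mean_h if mean_h > 0 else 0.0
    return c_f, c_h


def _af_median(d):
    """Size-dependent asymmetry-factor median: ~5 below 2.5 um, 10-20 above 5 um."""
    pts_d = np.log([0.5, 2.5, 5.0, 14.0, 16.0])
    pts_af = np.array([5.0, 5.0, 10.0, 16.0, 17.0])
    return np.interp(np.log(d), pts_d, pts_af)


# ---------------------------------------------------------------------------
# ground truth & campaign containers


@dataclass
class GroundTruth:
    """Per-particle and per-bin truth carried alongside the observables."""

    particle_tier: np.ndarray        # int8, 0 none / 1 fluorescent / 2 hyper
    particle_population: np.ndarray  # int8, codes into POPULATION_NAMES
    bin_table: pd.DataFrame          # per 5-min bin emission parameters

    def __post_init__(self):
        assert self.particle_tier.shape == self.particle_population.shape


@dataclass
class Campaign:
    """A complete synthetic campaign: observables plus ground truth."""

    preset: ScenarioPreset
    particles: pd.DataFrame
    track: pd.DataFrame
    coastline: np.ndarray
    ft_records: pd.DataFrame
    proxies: pd.DataFrame
    marine: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# the generator


def _ship_track(preset: ScenarioPreset, bin_t_h: np.ndarray, rng) -> pd.DataFrame:
    """Scenario ship path at 5-min resolution plus AR(1) wind."""
    frac = bin_t_h / preset.duration_h
    if preset.coastline_scenario == "meridian-coast":
        # mostly far-field (~700 km off the lon-0 coast) with one sustained
        # coastal excursion (~20-120 km) mid-campaign, so distance thresholds
        # beyond the plume leave an essentially fixed pristine subset
        lat = np.full(frac.shape, -55.0)
        c0 = 0.5 * (preset.dwell_min_km + preset.dwell_max_km)
        amp = 0.5 * (preset.dwell_max_km - preset.dwell_min_km)
        d_km = np.interp(
            frac, [0.0, 0.45, 0.46, 0.60, 0.61, 1.0], [700.0, 640.0, c0, c0, 640.0, 700.0]
        )
        far = (frac < 0.45) | (frac >= 0.61)
        d_km = d_km + 40.0 * np.sin(8.0 * np.pi * frac) * far
        dwell = (frac >= 0.46) & (frac < 0.60)
        d_km = np.where(
            dwell, c0 + amp * np.sin(2.0 * np.pi * 3.0 * (frac - 0.46) / 0.14), d_km
        )
        lon = -d_km / 63.77  # km per degree longitude at 55S
    else:
        # open-ocean circumnavigation-like sweep
        lat = -55.0 + 8.0 * np.sin(2.0 * np.pi * 2.0 * frac)
        lon = -180.0 + 360.0 * frac
        lon = ((lon + 180.0) % 360.0) - 180.0
    n_bins = bin_t_h.size
    tau_bins = preset.wind_tau_h * 60.0 / preset.time_bin_min
    u10n = preset.wind_median_ms * np.exp(
        _ar1_log(rng, n_bins, preset.wind_sigma_log, tau_bins)
    )
    t = CAMPAIGN_START + pd.to_timedelta(bin_t_h, unit="h")
    return pd.DataFrame({"timestamp": t, "lat": lat, "lon": lon, "u10n": u10n})


def _emit_block(
    rng_sizes, rng_tier, rng_pat, rng_amp, rng_af, rng_t,
    counts, bin_start_s, dt_s, size_median, preset,
    thr3, thr9, ft_means, ft_sds,
    p_f_of_d, p_h_of_d, terrestrial: bool,
):
    """Draw one particle block (marine or terrestrial), fully vectorised."""
    n = int(counts.sum())
    cols = {}
    bin_idx = np.repeat(np.arange(counts.size), counts)
    t_s = bin_start_s[bin_idx] + rng_t.random(n) * dt_s
    d = _trunc_lognormal(
        rng_sizes, n, size_median, preset.size_sigma_log, *preset.size_range_um
    )
    # tier assignment: one uniform per particle; hyper prob <= fluor prob
    p_f = p_f_of_d(d, bin_idx)
    p_h = np.minimum(p_f, p_h_of_d(d, bin_idx))
    u = rng_tier.random(n)
    hyper = u < p_h
    fluor = u < p_f  # superset of hyper
    tier = np.zeros(n, dtype=np.int8)
    tier[fluor] = TIER_CODE_FLUOR
    tier[hyper] = TIER_CODE_HYPER
    if terrestrial:
        pop = np.full(n, POP_TERRESTRIAL, dtype=np.int8)
        pat_probs_f = _PATTERN_PROBS["terrestrial"]
        pat_probs_h = _PATTERN_PROBS["terrestrial"]
    else:
        pop = np.full(n, POP_SSA_BACKGROUND, dtype=np.int8)
        pop[fluor] = POP_BACTERIA_LIKE
        pop[hyper] = POP_PHYTOPLANKTON_LIKE
        pat_probs_f = _PATTERN_PROBS["marine_fluor"]
        pat_probs_h = _PATTERN_PROBS["marine_hyper"]
    # Amplitudes: background everywhere, overwrite lit channels of emitters.
    # Bands keep a 0.5-SD guard away from the exact 3σ/9σ cutoffs so that the
    # pipeline's thresholds (re-estimated from finite FT samples) classify
    # every particle into its ground-truth tier.
    guard = 0.5 * ft_sds
    fl = np.empty((n, 3), dtype=np.float64)
    for i in range(3):
        bg = rng_amp.normal(ft_means[i], ft_sds[i], size=n)
        hi_clip = thr3[i] - max(guard[i], 1e-6 * (1.0 + abs(thr3[i])))
        fl[:, i] = np.clip(bg, 0.0, max(hi_clip, 0.0))
    fluor_only = fluor & ~hyper
    for mask, probs, lo, hi in (
        (fluor_only, pat_probs_f, thr3 + guard, thr9 - guard),
        (hyper, pat_probs_h, thr9 + guard, np.full(3, np.inf)),
    ):
        k = int(mask.sum())
        if k == 0:
            continue
        codes = rng_pat.choice(_PATTERN_CODES, size=k, p=probs / probs.sum())
        for i in range(3):
            lit = (codes >> i) & 1 == 1
            m = int(lit.sum())
            if m == 0:
                continue
            lo_i = lo[i]
            hi_i = hi[i]
            if not np.isfinite(hi_i):
                med = 1.5 * max(lo_i, 1e-6)
                amp = _trunc_lognormal(rng_amp, m, med, 0.5, lo=lo_i)
            else:
                if hi_i <= lo_i:  # degenerate zero-SD band
                    amp = np.full(m, lo_i * 1.5 + 1.0)
                else:
                    med = np.sqrt(max(lo_i, 1e-6) * hi_i)
                    amp = _trunc_lognormal(rng_amp, m, med, 0.4, lo=lo_i, hi=hi_i)
            rows = np.flatnonzero(mask)[lit]
            fl[rows, i] = amp
    af = np.exp(rng_af.normal(np.log(_af_median(d)), 0.35))
    cols["t_s"] = t_s
    cols["d_opt"] = d.astype(np.float32)
    cols["af"] = af.astype(np.float32)
    cols["fl_a"] = fl[:, 0].astype(np.float32)
    cols["fl_b"] = fl[:, 1].astype(np.float32)
    cols["fl_c"] = fl[:, 2].astype(np.float32)
    return cols, tier, pop, bin_idx


def generate_campaign(preset: ScenarioPreset, seed=None) -> Campaign:
    """Generate a full synthetic campaign for the given scenario preset.

    ``seed`` overrides ``preset.seed``.  Regeneration with the same preset and
    seed is bit-identical.
    """
    base_seed = preset.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    (ss_wind, ss_frac, ss_counts, ss_sizes, ss_tier, ss_pat, ss_amp, ss_af,
     ss_t, ss_ft, ss_marine, ss_proxy, ss_terr) = ss.spawn(13)

    dt_min = preset.time_bin_min
    dt_s = dt_min * 60.0
    n_bins = int(round(preset.duration_h * 60.0 / dt_min))
    bin_t_h = np.arange(n_bins) * dt_min / 60.0
    bin_start_s = bin_t_h * 3600.0

    rng_wind = np.random.default_rng(ss_wind)
    track = _ship_track(preset, bin_t_h, rng_wind)

    coastline = generate_coastline(preset.coastline_scenario)
    if coastline.shape[0]:
        from .geospatial import distance_to_land

        d_land = distance_to_land(track, coastline)
    else:
        d_land = np.full(n_bins, np.inf)

    # biological modulation of the fluorescent fractions (median-1 lognormals)
    rng_frac = np.random.default_rng(ss_frac)
    tau_bins = preset.frac_tau_h * 60.0 / dt_min
    z_f = _ar1_log(rng_frac, n_bins, 1.0, tau_bins)
    z_h_ind = _ar1_log(rng_frac, n_bins, 1.0, tau_bins)
    rho = preset.frac_signal_corr
    z_h = rho * z_f + np.sqrt(1.0 - rho**2) * z_h_ind
    m_f = np.exp(preset.frac_sigma_log * z_f)
    m_h = np.exp(preset.frac_sigma_log * z_h)

    # coarse concentration per bin (median = base at median wind)
    rng_counts = np.random.default_rng(ss_counts)
    u = track["u10n"].to_numpy()
    conc_coarse = (
        preset.base_coarse_conc
        * (u / preset.wind_median_ms) ** preset.wind_coupling
        * np.exp(rng_counts.normal(0.0, preset.conc_noise_log, size=n_bins))
    )
    # total (fine+coarse) rate: sizes are drawn from the full truncated
    # lognormal, so scale by the coarse probability of that distribution
    mu, s = np.log(preset.size_median_um), preset.size_sigma_log
    lo, hi = preset.size_range_um
    p_in = ndtr((np.log(hi) - mu) / s) - ndtr((np.log(lo) - mu) / s)
    p_coarse = (ndtr((np.log(hi) - mu) / s) - ndtr((np.log(1.0) - mu) / s)) / p_in
    vol_l = preset.sample_flow_l_min * dt_min
    lam_marine = conc_coarse / p_coarse * vol_l
    counts_marine = rng_counts.poisson(lam_marine)

    c_f, c_h = _calibrate_scales(preset)

    ft_records = generate_ft_records(
        preset.n_ft_records, preset.ft_means, preset.ft_sds,
        seed=np.random.default_rng(ss_ft).integers(2**31),
    )
    ft_means = np.asarray(preset.ft_means, dtype=float)
    ft_sds = np.asarray(preset.ft_sds, dtype=float)
    thr3 = ft_means + 3.0 * ft_sds
    thr9 = ft_means + 9.0 * ft_sds

    def p_f_marine(d, bin_idx):
        return np.minimum(0.95, c_f * _fluor_ramp(d, preset) * m_f[bin_idx])

    def p_h_marine(d, bin_idx):
        return np.minimum(0.95, c_h * _hyper_ramp(d, preset) * m_h[bin_idx])

    blocks = []
    cols, tier, pop, bin_idx = _emit_block(
        np.random.default_rng(ss_sizes), np.random.default_rng(ss_tier),
        np.random.default_rng(ss_pat), np.random.default_rng(ss_amp),
        np.random.default_rng(ss_af), np.random.default_rng(ss_t),
        counts_marine, bin_start_s, dt_s, preset.size_median_um, preset,
        thr3, thr9, ft_means, ft_sds, p_f_marine, p_h_marine, terrestrial=False,
    )
    blocks.append((cols, tier, pop, bin_idx))

    conc_terr = np.zeros(n_bins)
    if preset.terrestrial_coast_conc > 0 and np.isfinite(d_land).any():
        conc_terr = preset.terrestrial_coast_conc * np.exp(
            -np.where(np.isfinite(d_land), d_land, np.inf) / preset.terrestrial_decay_km
        )
        rng_terr = np.random.default_rng(ss_terr)
        if preset.terrestrial_noise_log > 0:
            tau_t = preset.terrestrial_noise_tau_h * 60.0 / dt_min
            conc_terr = conc_terr * np.exp(
                _ar1_log(rng_terr, n_bins, preset.terrestrial_noise_log, tau_t)
            )
        terr_seeds = ss_terr.spawn(6)
        counts_terr = rng_terr.poisson(conc_terr / p_coarse * vol_l)
        pf_t = preset.terrestrial_fluor_prob
        ph_t = preset.terrestrial_hyper_prob
        cols_t, tier_t, pop_t, bin_idx_t = _emit_block(
            *(np.random.default_rng(s) for s in terr_seeds),
            counts_terr, bin_start_s, dt_s, preset.terrestrial_size_median_um,
            preset, thr3, thr9, ft_means, ft_sds,
            lambda d, b: np.full(d.shape, pf_t),
            lambda d, b: np.full(d.shape, ph_t),
            terrestrial=True,
        )
        blocks.append((cols_t, tier_t, pop_t, bin_idx_t))

    t_s = np.concatenate([b[0]["t_s"] for b in blocks])
    order = np.argsort(t_s, kind="stable")
    # microsecond resolution: the interchange CSV format's time precision
    data = {"timestamp": CAMPAIGN_START + pd.to_timedelta(t_s[order], unit="s").round("us")}
    for key in ("d_opt", "af", "fl_a", "fl_b", "fl_c"):
        data[key] = np.concatenate([b[0][key] for b in blocks])[order]
    tier = np.concatenate([b[1] for b in blocks])[order]
    pop = np.concatenate([b[2] for b in blocks])[order]
    bin_idx_all = np.concatenate([b[3] for b in blocks])[order]

    flags = np.zeros(t_s.size, dtype=np.int64)
    if preset.contaminated_time_fraction > 0:
        f0, f1 = 0.3, 0.3 + preset.contaminated_time_fraction
        lo_b, hi_b = int(f0 * n_bins), int(f1 * n_bins)
        flags[(bin_idx_all >= lo_b) & (bin_idx_all < hi_b)] = FLAG_CONTAMINATED
    data["quality_flags"] = flags
    particles = pd.DataFrame(data)

    bin_table = pd.DataFrame(
        {
            "timestamp": track["timestamp"],
            "conc_coarse_true": conc_coarse,
            "conc_terrestrial_true": conc_terr,
            "m_fluor": m_f,
            "m_hyper": m_h,
            "distance_to_land_km": d_land,
            "u10n": u,
        }
    )
    truth = GroundTruth(particle_tier=tier, particle_population=pop, bin_table=bin_table)

    proxies = _proxy_series(preset, track, conc_coarse + conc_terr, np.random.default_rng(ss_proxy))
    marine = _marine_samples(preset, bin_t_h, z_f, z_h, np.random.default_rng(ss_marine))

    return Campaign(
        preset=preset,
        particles=particles,
        track=track,
        coastline=coastline,
        ft_records=ft_records,
        proxies=proxies,
        marine=marine,
        truth=truth,
    )


def _proxy_series(preset, track, conc_total, rng) -> pd.DataFrame:
    """Hourly SSA-proxy series (coarse conc, chloride) + 24-h sodium filters."""
    df = pd.DataFrame(
        {"timestamp": track["timestamp"], "conc": conc_total, "u10n": track["u10n"]}
    ).set_index("timestamp")
    hourly = df.resample("1h").mean()
    rows = []
    for t, row in hourly.iterrows():
        rows.append((t, "u10n", row["u10n"], "1h"))
        rows.append((t, "coarse_number_conc", row["conc"] * np.exp(rng.normal(0, 0.10)), "1h"))
        rows.append((t, "chloride", 0.02 * row["conc"] * np.exp(rng.normal(0, 0.30)), "1h"))
    daily = df.resample("24h").mean()
    for t, row in daily.iterrows():
        rows.append((t, "sodium", 0.03 * row["conc"] * np.exp(rng.normal(0, 0.20)), "24h"))
    return pd.DataFrame(rows, columns=["timestamp", "variable", "value", "averaging_window"])


def _marine_samples(preset, bin_t_h, z_f, z_h, rng) -> pd.DataFrame:
    """Seawater point samples coupled to the true fluorescent-fraction signals
    through a Gaussian copula with per-variable correlation."""
    step = int(round(preset.marine_interval_h * 60.0 / preset.time_bin_min))
    idx = np.arange(0, bin_t_h.size, max(step, 1))
    t = CAMPAIGN_START + pd.to_timedelta(bin_t_h[idx], unit="h")
    rows = []
    for name, category, signal, rho, median, sigma in _MARINE_VARIABLES:
        z_sig = z_f[idx] if signal == "fluor" else z_h[idx]
        eps = rng.normal(0.0, 1.0, size=idx.size)
        z = rho * z_sig + np.sqrt(1.0 - rho**2) * eps
        vals = median * np.exp(sigma * z)
        for ti, v in zip(t, vals):
            rows.append((ti, name, v, category))
    return pd.DataFrame(rows, columns=["timestamp", "variable", "value", "category"])
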