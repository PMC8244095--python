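"""Summary products from labelled particle streams.

Turns single-particle records plus tier labels into the campaign-level
quantities of interest: number concentrations (particles per litre of sampled
air), fluorescent/hyper-fluorescent number fractions per time bin, log-binned
optical size distributions (dN/dlogD), size-resolved fluorescent fractions,
asymmetry-factor probability densities per size class, and latitudinal box
statistics.

Conventions fixed here (and relied on by the tests): the fine/coarse split is
at an optical diameter of 1 µm with the boundary particle counted as coarse;
empty-bin fractions are reported as missing (NaN), never as zero; particles
falling outside a size grid are tallied as overflow, never silently lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .particle_io import bin_starts

#: default optical-size grid: 16 logarithmically spaced bins, 0.5–16 µm
DEFAULT_SIZE_EDGES = np.logspace(np.log10(0.5), np.log10(16.0), 17)

#: default asymmetry-factor size classes (µm) mirroring the reporting ranges
DEFAULT_AF_SIZE_CLASSES = ((0.5, 2.5), (2.5, 5.0), (5.0, 14.0))

#: WIBS sample flow in litres per minute (configurable everywhere it is used)
DEFAULT_SAMPLE_FLOW_L_MIN = 0.23

COARSE_SPLIT_UM = 1.0

__all__ = [
    "DEFAULT_SIZE_EDGES",
    "DEFAULT_AF_SIZE_CLASSES",
    "DEFAULT_SAMPLE_FLOW_L_MIN",
    "number_concentration",
    "split_fine_coarse",
    "time_binned_series",
    "SizeDistribution",
    "size_distribution",
    "median_size_distribution",
    "size_resolved_fraction",
    "AFDistribution",
    "af_pdf",
    "latitude_binning",
]


def number_concentration(count, flow_l_min: float, duration_min: float):
    """Counts → particles per litre: count / (flow × duration)."""
    if flow_l_min <= 0 or duration_min <= 0:
        raise ValueError("flow and duration must be positive")
    return np.asarray(count, dtype=float) / (flow_l_min * duration_min)


def split_fine_coarse(particles: pd.DataFrame):
    """Partition at d_opt = 1 µm; the boundary particle goes to coarse."""
    coarse = particles["d_opt"].to_numpy(dtype=float) >= COARSE_SPLIT_UM
    return particles.loc[~coarse], particles.loc[coarse]


def time_binned_series(
    particles: pd.DataFrame,
    in_tier_3: np.ndarray,
    in_tier_9: np.ndarray,
    bin_width="1h",
    flow_l_min: float = DEFAULT_SAMPLE_FLOW_L_MIN,
) -> pd.DataFrame:
    """Per-time-bin coarse counts, concentrations and fluorescent fractions.

    Only coarse particles (d_opt >= 1 µm) enter the counts; ``in_tier_3`` /
    ``in_tier_9`` are boolean arrays aligned with ``particles`` (3σ fluorescent
    and 9σ hyper-fluorescent tier membership).  Fractions in bins with zero
    coarse particles are NaN.  The index is the bin start; bins with no
    particles at all between the first and last occupied bin are filled with
    zero counts.
    """
    w = pd.Timedelta(bin_width)
    duration_min = w.total_seconds() / 60.0
    coarse = particles["d_opt"].to_numpy(dtype=float) >= COARSE_SPLIT_UM
    starts = bin_starts(particles["timestamp"], w)
    f3 = np.asarray(in_tier_3, dtype=bool) & coarse
    f9 = np.asarray(in_tier_9, dtype=bool) & coarse
    g = pd.DataFrame(
        {"bin": starts.to_numpy(), "coarse": coarse, "f3": f3, "f9": f9}
    ).groupby("bin", sort=True)[["coarse", "f3", "f9"]].sum()
    full = pd.date_range(g.index.min(), g.index.max(), freq=w)
    g = g.reindex(full, fill_value=0)
    out = pd.DataFrame(index=full)
    out["n_total_coarse"] = g["coarse"].astype(int)
    out["n_fluor"] = g["f3"].astype(int)
    out["n_hyper"] = g["f9"].astype(int)
    out["conc_total_coarse"] = number_concentration(out["n_total_coarse"], flow_l_min, duration_min)
    out["conc_fluor"] = number_concentration(out["n_fluor"], flow_l_min, duration_min)
    out["conc_hyper"] = number_concentration(out["n_hyper"], flow_l_min, duration_min)
    with np.errstate(invalid="ignore", divide="ignore"):
        tot = out["n_total_coarse"].to_numpy(dtype=float)
        out["frac_fluor"] = np.where(tot > 0, out["n_fluor"] / tot, np.nan)
        out["frac_hyper"] = np.where(tot > 0, out["n_hyper"] / tot, np.nan)
    return out


@dataclass
class SizeDistribution:
    """Log-binned number size distribution.

    ``dndlogd`` is dN/dlog10(D) in L^-1 per size bin; the integral
    sum(dndlogd * dlog10(D)) recovers the total in-range concentration.
    Particles outside the grid are counted in ``n_overflow``.
    """

    edges_um: np.ndarray
    counts: np.ndarray
    dndlogd: np.ndarray
    n_overflow: int
    fluor_fraction: np.ndarray | None = None

    @property
    def centers_um(self) -> np.ndarray:
        return np.sqrt(self.edges_um[:-1] * self.edges_um[1:])

    @property
    def dlog(self) -> np.ndarray:
        return np.diff(np.log10(self.edges_um))

    @property
    def total_concentration(self) -> float:
        return float(np.sum(self.dndlogd * self.dlog))


def size_distribution(
    particles: pd.DataFrame,
    edges_um=DEFAULT_SIZE_EDGES,
    flow_l_min: float = DEFAULT_SAMPLE_FLOW_L_MIN,
    duration_min: float | None = None,
) -> SizeDistribution:
    """Histogram the optical diameters onto a log grid as dN/dlog10(D).

    ``duration_min`` defaults to the record time span (last − first timestamp);
    it must be supplied for single-bin toy streams.
    """
    edges_um = np.asarray(edges_um, dtype=float)
    if edges_um.size < 2 or np.any(np.diff(edges_um) <= 0):
        raise ValueError("size bin edges must be increasing with >= 1 bin")
    d = particles["d_opt"].to_numpy(dtype=float)
    if duration_min is None:
        ts = pd.to_datetime(particles["timestamp"])
        duration_min = (ts.max() - ts.min()).total_seconds() / 60.0
        if not duration_min > 0:
            raise ValueError("cannot infer a positive duration; pass duration_min")
    counts, _ = np.histogram(d, bins=edges_um)
    in_range = (d >= edges_um[0]) & (d < edges_um[-1])
    n_overflow = int(d.size - counts.sum())
    conc = number_concentration(counts, flow_l_min, duration_min)
    dndlogd = conc / np.diff(np.log10(edges_um))
    del in_range
    return SizeDistribution(
        edges_um=edges_um, counts=counts, dndlogd=dndlogd, n_overflow=n_overflow
    )


def median_size_distribution(
    particles: pd.DataFrame,
    edges_um=DEFAULT_SIZE_EDGES,
    time_bin="1h",
    flow_l_min: float = DEFAULT_SAMPLE_FLOW_L_MIN,
):
    """Median and IQR over per-time-bin size distributions.

    Returns a DataFrame indexed by bin centre with columns ``median``, ``q25``,
    ``q75`` (all dN/dlog10(D), L^-1).
    """
    w = pd.Timedelta(time_bin)
    duration_min = w.total_seconds() / 60.0
    edges_um = np.asarray(edges_um, dtype=float)
    starts = bin_starts(particles["timestamp"], w).to_numpy()
    uniq, inv = np.unique(starts, return_inverse=True)
    d = particles["d_opt"].to_numpy(dtype=float)
    idx = np.digitize(d, edges_um) - 1
    ok = (idx >= 0) & (idx < edges_um.size - 1)
    mat = np.zeros((uniq.size, edges_um.size - 1))
    np.add.at(mat, (inv[ok], idx[ok]), 1.0)
    mat = mat / (flow_l_min * duration_min) / np.diff(np.log10(edges_um))
    centers = np.sqrt(edges_um[:-1] * edges_um[1:])
    return pd.DataFrame(
        {
            "median": np.median(mat, axis=0),
            "q25": np.percentile(mat, 25, axis=0),
            "q75": np.percentile(mat, 75, axis=0),
        },
        index=pd.Index(centers, name="d_um"),
    )


def size_resolved_fraction(
    particles: pd.DataFrame, in_tier: np.ndarray, edges_um=DEFAULT_SIZE_EDGES
) -> pd.DataFrame:
    """Fluorescent fraction per size bin; empty bins are NaN (flagged missing)."""
    edges_um = np.asarray(edges_um, dtype=float)
    d = particles["d_opt"].to_numpy(dtype=float)
    fl = np.asarray(in_tier, dtype=bool)
    n_tot, _ = np.histogram(d, bins=edges_um)
    n_fl, _ = np.histogram(d[fl], bins=edges_um)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_tot > 0, n_fl / np.maximum(n_tot, 1), np.nan)
    centers = np.sqrt(edges_um[:-1] * edges_um[1:])
    return pd.DataFrame(
        {"n_total": n_tot, "n_fluor": n_fl, "fraction": frac},
        index=pd.Index(centers, name="d_um"),
    )


@dataclass
class AFDistribution:
    """Normalised asymmetry-factor histogram for one size class."""

    size_class_um: tuple
    af_edges: np.ndarray
    density: np.ndarray  # integrates to 1 over the AF axis
    n: int


def af_pdf(
    particles: pd.DataFrame,
    size_classes=DEFAULT_AF_SIZE_CLASSES,
    af_bins=None,
) -> list[AFDistribution]:
    """Per-size-class probability density of the asymmetry factor.

    Size classes are half-open [lo, hi); empty classes yield an all-NaN
    density (flagged, not zero).
    """
    if af_bins is None:
        af_bins = np.linspace(0.0, 50.0, 51)
    af_edges = np.asarray(af_bins, dtype=float)
    d = particles["d_opt"].to_numpy(dtype=float)
    af = particles["af"].to_numpy(dtype=float)
    out = []
    for lo, hi in size_classes:
        sel = (d >= lo) & (d < hi)
        n = int(sel.sum())
        if n == 0:
            dens = np.full(af_edges.size - 1, np.nan)
        else:
            dens, _ = np.histogram(af[sel], bins=af_edges, density=True)
        out.append(AFDistribution(size_class_um=(lo, hi), af_edges=af_edges, density=dens, n=n))
    return out


def latitude_binning(
    series: pd.Series,
    lats: np.ndarray,
    width_deg: float = 4.0,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Box statistics of ``series`` grouped in latitude intervals.

    Bins are half-open toward the pole the track is heading to (i.e.
    [edge, edge + width) on a southward grid anchored at a multiple of
    ``width_deg``).  Bins with fewer than ``min_samples`` points are flagged
    via the ``ok`` column (statistics still reported).
    """
    x = np.asarray(series, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if x.shape != lats.shape:
        raise ValueError("series and latitudes must be aligned")
    ok = np.isfinite(x) & np.isfinite(lats)
    x, lats = x[ok], lats[ok]
    lo = np.floor(lats.min() / width_deg) * width_deg
    idx = np.floor((lats - lo) / width_deg).astype(int)
    rows = []
    for i in np.unique(idx):
        v = x[idx == i]
        rows.append(
            {
                "lat_lo": lo + i * width_deg,
                "lat_hi": lo + (i + 1) * width_deg,
                "n": v.size,
                "median": np.median(v),
                "q25": np.percentile(v, 25),
                "q75": np.percentile(v, 75),
                "p05": np.percentile(v, 5),
                "p95": np.percentile(v, 95),
                "ok": v.size >= min_samples,
            }
        )
    return pd.DataFrame(rows)
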