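"""Paired-sample correlation machinery.

The aerosol–seawater analysis reduces to: pair each marine point sample with
the hourly aerosol average covering its timestamp, compute Pearson's R over
the pairs, attach an uncertainty from a 100-replicate 60% subsampling
bootstrap, and a two-sided permutation p-value.  Results with fewer than 25
simultaneous pairs are not considered reportable.  Binned median/IQR curves
(10 equidistant logarithmic bins) and the class-fraction subsampling
bootstraps used for the ABC composition robustness checks live here too.

Subsampling draws are *without* replacement within each replicate; the
permutation test uses the add-one correction p = (1 + #{|r*| >= |r|}) / (1 + B)
so p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIN_PAIRS = 25

__all__ = [
    "MIN_PAIRS",
    "pearson_r",
    "pair_marine_to_aerosol",
    "BootstrapSummary",
    "bootstrap_r",
    "permutation_p",
    "binned_median_iqr",
    "class_fraction_bootstrap",
    "CorrelationResult",
    "correlate_pairs",
]


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient.

    Requires n >= 3 and nonzero variance in both arguments (undefined
    otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.sum(dx * dx))
    sy = np.sqrt(np.sum(dy * dy))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("Pearson r undefined for zero-variance input")
    return float(np.clip(np.sum(dx * dy) / (sx * sy), -1.0, 1.0))


def pair_marine_to_aerosol(
    marine: pd.DataFrame,
    aerosol_hourly: pd.DataFrame,
    aerosol_column: str,
    value_column: str = "value",
):
    """Join marine point samples to the hourly aerosol bin containing them.

    ``aerosol_hourly`` must be indexed by hourly bin starts.  Samples falling
    in hours with no (finite) aerosol data are dropped and counted.  Returns
    ``(pairs, n_dropped)`` where pairs has columns ``marine`` and ``aerosol``.
    """
    hours = pd.to_datetime(marine["timestamp"]).dt.floor("1h")
    aero = aerosol_hourly[aerosol_column]
    matched = hours.map(aero)
    ok = matched.notna().to_numpy()
    pairs = pd.DataFrame(
        {
            "timestamp": marine["timestamp"].to_numpy()[ok],
            "marine": marine[value_column].to_numpy(dtype=float)[ok],
            "aerosol": matched.to_numpy(dtype=float)[ok],
        }
    )
    return pairs, int((~ok).sum())


@dataclass
class BootstrapSummary:
    """Subsampling distribution of Pearson's R."""

    r_values: np.ndarray
    n_discarded: int
    interval_level: float = 0.9

    @property
    def mean(self) -> float:
        return float(np.mean(self.r_values))

    @property
    def sd(self) -> float:
        return float(np.std(self.r_values, ddof=1)) if self.r_values.size > 1 else 0.0

    @property
    def interval(self) -> tuple[float, float]:
        a = 100.0 * (1.0 - self.interval_level) / 2.0
        return (
            float(np.percentile(self.r_values, a)),
            float(np.percentile(self.r_values, 100.0 - a)),
        )


def bootstrap_r(x, y, n_rep: int = 100, frac: float = 0.6, seed=None) -> BootstrapSummary:
    """Subsampling bootstrap of Pearson's R.

    Each of the ``n_rep`` replicates recomputes R on a random ``frac`` subset
    of the pairs drawn without replacement.  Replicates whose subsample has
    zero variance in either variable are discarded and counted.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} pairs, got {n}")
    m = max(3, int(round(frac * n)))
    vals, discarded = [], 0
    for _ in range(n_rep):
        idx = rng.choice(n, size=m, replace=False)
        try:
            vals.append(pearson_r(x[idx], y[idx]))
        except ValueError:
            discarded += 1
    return BootstrapSummary(r_values=np.asarray(vals), n_discarded=discarded)


def permutation_p(x, y, n_perm: int = 10_000, seed=None) -> float:
    """Two-sided permutation p-value for Pearson's R.

    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), permuting y against x.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = pearson_r(x, y)
    n = x.size
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    r_perm = (zy[perms] @ zx) / (n - 1)
    more_extreme = int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    return (1 + more_extreme) / (1 + n_perm)


def binned_median_iqr(x, y, n_bins: int = 10, min_count: int = 5) -> pd.DataFrame:
    """Median and IQR of y in equidistant logarithmic bins of x.

    Requires strictly positive x.  Bins with fewer than ``min_count`` points
    are flagged via the ``ok`` column.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ValueError("log binning requires strictly positive x")
    lx = np.log10(x)
    edges = np.linspace(lx.min(), lx.max(), n_bins + 1)
    idx = np.clip(np.digitize(lx, edges) - 1, 0, n_bins - 1)
    rows = []
    for i in range(n_bins):
        v = y[idx == i]
        rows.append(
            {
                "x_lo": 10 ** edges[i],
                "x_hi": 10 ** edges[i + 1],
                "n": v.size,
                "median": np.median(v) if v.size else np.nan,
                "q25": np.percentile(v, 25) if v.size else np.nan,
                "q75": np.percentile(v, 75) if v.size else np.nan,
                "ok": v.size >= min_count,
            }
        )
    return pd.DataFrame(rows)


def class_fraction_bootstrap(
    fraction_table: pd.DataFrame,
    mode: str = "fixed_count",
    n_rep: int = 100,
    sample_size: int = 288,
    window: str = "24h",
    min_coverage: str = "12h",
    time_bin: str = "5min",
    seed=None,
) -> pd.DataFrame:
    """Subsampling bootstrap of ABC class-fraction medians.

    ``fraction_table`` holds one row per (5-min) data point and one column per
    ABC class fraction, indexed by timestamp.  Two modes:

    * ``"fixed_count"`` — each replicate draws ``sample_size`` rows without
      replacement (288 rows of 5-min data = 12 h of measurements);
    * ``"window_24h"`` — each replicate picks a random fixed-length window
      (default 24 h) that contains at least ``min_coverage`` worth of rows.

    Returns a (n_rep × classes) DataFrame of per-replicate median fractions.
    Raises if no window qualifies / not enough rows.
    """
    rng = np.random.default_rng(seed)
    tbl = fraction_table.sort_index()
    n = len(tbl)
    reps = []
    if mode == "fixed_count":
        if n < sample_size:
            raise ValueError(f"need >= {sample_size} data points, got {n}")
        for _ in range(n_rep):
            idx = rng.choice(n, size=sample_size, replace=False)
            reps.append(tbl.iloc[idx].median(axis=0))
    elif mode == "window_24h":
        w = pd.Timedelta(window)
        need = int(pd.Timedelta(min_coverage) / pd.Timedelta(time_bin))
        ts = tbl.index
        starts = [t for t in ts if ((ts >= t) & (ts < t + w)).sum() >= need]
        if not starts:
            raise ValueError(f"no {window} window contains {min_coverage} of data")
        for _ in range(n_rep):
            t0 = starts[rng.integers(len(starts))]
            sel = tbl.loc[(ts >= t0) & (ts < t0 + w)]
            reps.append(sel.median(axis=0))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame(reps).reset_index(drop=True)
    out.index.name = "replicate"
    return out


@dataclass
class CorrelationResult:
    """Paired-sample Pearson R with bootstrap spread and permutation p."""

    pair: tuple[str, str]
    n_pairs: int
    r: float
    p_perm: float
    bootstrap: BootstrapSummary
    significance_level: float = 0.10
    significant: bool = field(init=False)

    def __post_init__(self):
        self.significant = self.p_perm < self.significance_level

    def to_row(self) -> dict:
        lo, hi = self.bootstrap.interval
        return {
            "var_x": self.pair[0],
            "var_y": self.pair[1],
            "n_pairs": self.n_pairs,
            "r": self.r,
            "p_perm": self.p_perm,
            "bootstrap_sd": self.bootstrap.sd,
            "bootstrap_lo": lo,
            "bootstrap_hi": hi,
            "significant_90": self.significant,
        }


def correlate_pairs(
    x,
    y,
    labels=("x", "y"),
    n_boot: int = 100,
    boot_frac: float = 0.6,
    n_perm: int = 10_000,
    seed=None,
) -> CorrelationResult:
    """Full correlation analysis on one pair of aligned samples.

    Enforces the >= 25 simultaneous pairs rule; the bootstrap and permutation
    draws are seeded independently but reproducibly from ``seed``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} pairs, got {x.size}")
    ss = np.random.SeedSequence(seed)
    s_boot, s_perm = ss.spawn(2)
    return CorrelationResult(
        pair=tuple(labels),
        n_pairs=int(x.size),
        r=pearson_r(x, y),
        p_perm=permutation_p(x, y, n_perm=n_perm, seed=s_perm),
        bootstrap=bootstrap_r(x, y, n_rep=n_boot, frac=boot_frac, seed=s_boot),
    )
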