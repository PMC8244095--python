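"""Versioned CSV interchange for particle streams, ship tracks, proxies and
marine samples, plus time binning.

All tables are plain CSV with a ``#``-comment header naming the schema and the
units; the canonical column sets are in :data:`SCHEMAS`.  Readers are
conservative: rows whose mandatory fields fail to parse (or violate the basic
physical range checks) are dropped and counted in a rejection report — never
silently lost — while a missing mandatory *column* is an error naming the
column.  Writers and readers round-trip valid data losslessly.

Time bins are half-open, left-closed UTC intervals [t, t + width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

#: mandatory columns per table kind
SCHEMAS = {
    "particles": ["timestamp", "d_opt", "af", "fl_a", "fl_b", "fl_c", "quality_flags"],
    "track": ["timestamp", "lat", "lon", "u10n"],
    "marine": ["timestamp", "variable", "value", "category"],
    "proxies": ["timestamp", "variable", "value", "averaging_window"],
}

_UNITS = {
    "particles": "timestamp UTC; d_opt um; af -; fl_a/fl_b/fl_c instrument units; quality_flags bit set",
    "track": "timestamp UTC; lat/lon deg; u10n m s-1 (10-m neutral)",
    "marine": "timestamp UTC; value variable-specific; category one of microbe_count/taxa_mass/OM",
    "proxies": "timestamp UTC; value variable-specific; averaging_window 1h or 24h",
}

__all__ = [
    "SCHEMAS",
    "RejectionReport",
    "read_table",
    "write_table",
    "read_particles",
    "write_particles",
    "read_track",
    "write_track",
    "read_marine",
    "write_marine",
    "read_proxies",
    "write_proxies",
    "normalise_lon",
    "align_to_bins",
    "bin_starts",
]


@dataclass
class RejectionReport:
    """Accounting of rows dropped while reading: accepted + rejected = input."""

    n_input: int
    n_accepted: int
    n_rejected: int

    def __post_init__(self):
        assert self.n_accepted + self.n_rejected == self.n_input


def _write(df: pd.DataFrame, path, kind: str) -> None:
    cols = SCHEMAS[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table missing mandatory column(s): {missing}")
    out = df[cols].copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].astype(np.float64)  # shortest-roundtrip repr
    ts = pd.to_datetime(out["timestamp"])
    out["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# pbapflow {kind} schema v{SCHEMA_VERSION}\n")
        fh.write(f"# units: {_UNITS[kind]}\n")
        # repr of the Python float is the shortest exact-round-trip form
        out.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def _read(path, kind: str, numeric: list[str], validators=None):
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table at {path} missing mandatory column(s): {missing}")
    n_in = len(df)
    ok = np.ones(n_in, dtype=bool)
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    ok &= ts.notna().to_numpy()
    parsed = {"timestamp": ts}
    for col in numeric:
        x = pd.to_numeric(df[col], errors="coerce")
        good = x.notna()
        ok &= good.to_numpy()
        # re-parse through numpy for correctly-rounded (round-trip) floats
        parsed[col] = df[col].where(good, np.nan).astype(np.float64)
    for col in SCHEMAS[kind]:
        if col not in parsed:
            parsed[col] = df[col]
    out = pd.DataFrame(parsed)[SCHEMAS[kind]]
    if validators:
        for fn in validators:
            ok &= fn(out).to_numpy() if hasattr(fn(out), "to_numpy") else fn(out)
    out = out.loc[ok].reset_index(drop=True)
    return out, RejectionReport(n_input=n_in, n_accepted=len(out), n_rejected=int(n_in - ok.sum()))


def write_particles(particles: pd.DataFrame, path) -> None:
    _write(particles, path, "particles")


def read_particles(path):
    """Read a particle table; returns ``(DataFrame, RejectionReport)``."""
    df, rep = _read(
        path,
        "particles",
        numeric=["d_opt", "af", "fl_a", "fl_b", "fl_c", "quality_flags"],
        validators=[
            lambda d: (d["d_opt"] > 0) & (d["d_opt"] <= 20.0),
            lambda d: d["af"] >= 0,
            lambda d: (d["fl_a"] >= 0) & (d["fl_b"] >= 0) & (d["fl_c"] >= 0),
        ],
    )
    df["quality_flags"] = df["quality_flags"].astype(np.int64)
    return df, rep


def normalise_lon(lon):
    """Normalise longitudes to the interval (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = ((lon + 180.0) % 360.0) - 180.0
    return np.where(out == -180.0, 180.0, out)


def write_track(track: pd.DataFrame, path) -> None:
    _write(track, path, "track")


def read_track(path):
    df, rep = _read(
        path,
        "track",
        numeric=["lat", "lon", "u10n"],
        validators=[lambda d: d["lat"].abs() <= 90.0],
    )
    df["lon"] = normalise_lon(df["lon"].to_numpy())
    return df, rep


def write_marine(marine: pd.DataFrame, path) -> None:
    _write(marine, path, "marine")


def read_marine(path):
    return _read(path, "marine", numeric=["value"], validators=[lambda d: d["value"] >= 0])


def write_proxies(proxies: pd.DataFrame, path) -> None:
    _write(proxies, path, "proxies")


def read_proxies(path):
    return _read(path, "proxies", numeric=["value"])


# generic aliases used by the CLI
def read_table(path, kind: str):
    return {
        "particles": read_particles,
        "track": read_track,
        "marine": read_marine,
        "proxies": read_proxies,
    }[kind](path)


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    _write(df, path, kind)


def bin_starts(timestamps, bin_width) -> pd.Series:
    """Left edge of the half-open bin [t, t+w) containing each timestamp."""
    w = pd.Timedelta(bin_width)
    if w <= pd.Timedelta(0):
        raise ValueError("bin_width must be positive")
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps)))
    return ts.dt.floor(w)


def align_to_bins(df: pd.DataFrame, bin_width, column: str = "timestamp"):
    """Group records into half-open time bins [t, t+w).

    Input order is irrelevant (sorted internally); duplicated timestamps are
    permitted.  Returns a pandas GroupBy keyed by bin start, so every record
    lands in exactly one group.
    """
    starts = bin_starts(df[column], bin_width)
    starts.index = df.index
    return df.sort_values(column).groupby(starts.rename("bin_start"), sort=True)
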