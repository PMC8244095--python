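"""Fluorescence thresholds, tiering, ABC classification and the R_B2A ratio.

The WIBS-4 records, for every detected particle, fluorescence amplitudes in
three excitation/emission channels:

* channel A — excitation 280 nm, emission 310–400 nm (protein-like band),
* channel B — excitation 280 nm, emission 420–650 nm (humic-like band),
* channel C — excitation 370 nm, emission 420–650 nm.

Detection thresholds are derived from "forced trigger" (FT) records: background
acquisitions with no particle in the beam.  A channel counts as "on" when its
amplitude strictly exceeds the FT mean plus k FT standard deviations; k = 3
defines the *fluorescent* tier and k = 9 the *hyper-fluorescent* tier (the
hyper tier is by construction a subset of the fluorescent tier).  The on/off
pattern over the three channels maps a particle to one of the seven ABC
classes (A, B, C, AB, AC, BC, ABC).

R_B2A is an approximate humification index: the ratio of channel-B to
channel-A amplitude, with sub-threshold amplitudes censored to the FT mean so
that detector noise cannot dominate the ratio.  High values indicate
humic-like, low values protein-like fluorophores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

CHANNELS = ("a", "b", "c")

#: excitation wavelength (nm), emission waveband (nm) per channel
CHANNEL_BANDS = {
    "a": {"excitation_nm": 280, "emission_nm": (310, 400)},
    "b": {"excitation_nm": 280, "emission_nm": (420, 650)},
    "c": {"excitation_nm": 370, "emission_nm": (420, 650)},
}

#: the 7 ABC classes, indexed by the 3-bit on-pattern (bit0=A, bit1=B, bit2=C)
ABC_CLASSES = ("none", "A", "B", "AB", "C", "AC", "BC", "ABC")

TIER_NONE = "none"
TIER_FLUOR = "fluorescent"
TIER_HYPER = "hyper_fluorescent"

__all__ = [
    "CHANNELS",
    "CHANNEL_BANDS",
    "ABC_CLASSES",
    "ThresholdSet",
    "compute_ft_stats",
    "classify_particles",
    "classify_particle",
    "compute_rb2a",
    "class_fractions",
    "apply_quality_mask",
    "register_mask",
    "FluorescenceLabel",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Per-channel forced-trigger statistics and derived 3σ/9σ cutoffs."""

    ft_mean: np.ndarray  # shape (3,), channels A, B, C
    ft_sd: np.ndarray    # shape (3,), sample SD (n-1 denominator)

    def __post_init__(self):
        object.__setattr__(self, "ft_mean", np.asarray(self.ft_mean, dtype=float))
        object.__setattr__(self, "ft_sd", np.asarray(self.ft_sd, dtype=float))
        if self.ft_mean.shape != (3,) or self.ft_sd.shape != (3,):
            raise ValueError("ft_mean and ft_sd must each have 3 channel entries")
        if np.any(self.ft_sd < 0):
            raise ValueError("FT standard deviations must be nonnegative")

    @property
    def t3(self) -> np.ndarray:
        return self.ft_mean + 3.0 * self.ft_sd

    @property
    def t9(self) -> np.ndarray:
        return self.ft_mean + 9.0 * self.ft_sd

    def tier_threshold(self, k: int) -> np.ndarray:
        if k == 3:
            return self.t3
        if k == 9:
            return self.t9
        raise ValueError(f"tier_k must be 3 or 9, got {k!r}")

    def to_dict(self) -> dict:
        d = {}
        for i, c in enumerate(CHANNELS):
            d[f"ft_mean_{c}"] = float(self.ft_mean[i])
            d[f"ft_sd_{c}"] = float(self.ft_sd[i])
            d[f"t3_{c}"] = float(self.t3[i])
            d[f"t9_{c}"] = float(self.t9[i])
        return d


def compute_ft_stats(ft_records: pd.DataFrame) -> ThresholdSet:
    """Derive the ThresholdSet from a forced-trigger record table.

    ``ft_records`` must have columns ``fl_a``, ``fl_b``, ``fl_c``; at least two
    finite records are required per channel (sample SD is undefined otherwise).
    """
    means, sds = [], []
    for c in CHANNELS:
        col = f"fl_{c}"
        if col not in ft_records.columns:
            raise ValueError(f"forced-trigger table missing column {col!r}")
        x = ft_records[col].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValueError(f"channel {c.upper()}: need >= 2 FT records, got {x.size}")
        means.append(x.mean())
        sds.append(x.std(ddof=1))
    return ThresholdSet(ft_mean=np.array(means), ft_sd=np.array(sds))


def _on_pattern(particles: pd.DataFrame, thr: np.ndarray) -> np.ndarray:
    """3-bit channel-exceedance pattern; exceedance is strict (>)."""
    code = np.zeros(len(particles), dtype=np.int8)
    for i, c in enumerate(CHANNELS):
        code |= (particles[f"fl_{c}"].to_numpy(dtype=float) > thr[i]).astype(np.int8) << i
    return code


def classify_particles(particles: pd.DataFrame, thresholds: ThresholdSet, tier_k: int) -> pd.DataFrame:
    """Classify a particle table at the given tier threshold (k = 3 or 9).

    Returns a DataFrame aligned with ``particles`` with columns:

    ``in_tier``   bool, at least one channel strictly above its kσ cutoff;
    ``abc_class`` categorical over ``ABC_CLASSES`` (``"none"`` off-tier).
    """
    thr = thresholds.tier_threshold(tier_k)
    code = _on_pattern(particles, thr)
    cls = pd.Categorical.from_codes(code, categories=list(ABC_CLASSES))
    return pd.DataFrame({"in_tier": code > 0, "abc_class": cls}, index=particles.index)


@dataclass(frozen=True)
class FluorescenceLabel:
    """Tier, ABC class and R_B2A of a single particle."""

    tier: str
    abc_class: str
    rb2a: float


def classify_particle(record, thresholds: ThresholdSet, tier_k: int) -> FluorescenceLabel:
    """Single-record convenience wrapper around :func:`classify_particles`."""
    df = pd.DataFrame([{f"fl_{c}": float(record[f"fl_{c}"]) for c in CHANNELS}])
    lab = classify_particles(df, thresholds, tier_k)
    in_tier = bool(lab["in_tier"].iloc[0])
    tier = (TIER_HYPER if tier_k == 9 else TIER_FLUOR) if in_tier else TIER_NONE
    rb2a = float(compute_rb2a(df, thresholds, tier_k)[0])
    return FluorescenceLabel(tier=tier, abc_class=str(lab["abc_class"].iloc[0]), rb2a=rb2a)


def compute_rb2a(particles: pd.DataFrame, thresholds: ThresholdSet, tier_k: int) -> np.ndarray:
    """Approximate humification index R_B2A = FL_B' / FL_A' per particle.

    FL_c' equals the measured amplitude when it strictly exceeds the tier's
    kσ cutoff in that channel and is censored to the channel's FT mean
    otherwise.  Requires a strictly positive channel-A FT mean.
    """
    thr = thresholds.tier_threshold(tier_k)
    if thresholds.ft_mean[0] <= 0:
        raise ValueError("R_B2A undefined: channel-A FT mean must be > 0")
    fa = particles["fl_a"].to_numpy(dtype=float)
    fb = particles["fl_b"].to_numpy(dtype=float)
    fa_c = np.where(fa > thr[0], fa, thresholds.ft_mean[0])
    fb_c = np.where(fb > thr[1], fb, thresholds.ft_mean[1])
    return fb_c / fa_c


def class_fractions(labels: pd.DataFrame) -> pd.Series:
    """Fraction of in-tier particles in each of the 7 ABC classes.

    ``labels`` is the output of :func:`classify_particles`.  Raises on an
    empty tier.  Fractions sum to 1.
    """
    in_tier = labels["in_tier"].to_numpy()
    if not in_tier.any():
        raise ValueError("no particles in tier: class fractions undefined")
    cls = labels.loc[labels["in_tier"], "abc_class"]
    counts = cls.value_counts().reindex(list(ABC_CLASSES[1:]), fill_value=0)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# quality masks (ship-exhaust style contamination screening, pluggable)

_MASK_REGISTRY: dict[str, Callable[[pd.DataFrame], np.ndarray]] = {}


def register_mask(name: str, predicate: Callable[[pd.DataFrame], np.ndarray]) -> None:
    """Register a named keep-predicate over the particle table."""
    _MASK_REGISTRY[name] = predicate


#: bit in ``quality_flags`` marking suspected (e.g. ship-exhaust) contamination
FLAG_CONTAMINATED = 0x1

register_mask("pass_all", lambda df: np.ones(len(df), dtype=bool))
register_mask(
    "flagged",
    lambda df: (df["quality_flags"].to_numpy(dtype=np.int64) & FLAG_CONTAMINATED) == 0,
)


def apply_quality_mask(particles: pd.DataFrame, mask_spec: str):
    """Drop records failing the named quality predicate.

    Returns ``(kept_table, report)`` where report holds the removed count and
    fraction.  Unknown mask names raise ``KeyError``.
    """
    if mask_spec not in _MASK_REGISTRY:
        raise KeyError(
            f"unknown quality mask {mask_spec!r}; known: {sorted(_MASK_REGISTRY)}"
        )
    keep = np.asarray(_MASK_REGISTRY[mask_spec](particles), dtype=bool)
    n = len(particles)
    removed = int(n - keep.sum())
    report = {
        "mask": mask_spec,
        "n_input": n,
        "n_removed": removed,
        "removed_fraction": (removed / n) if n else 0.0,
    }
    return particles.loc[keep], report
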