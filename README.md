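# pbapflow

Analysis pipeline for ship-borne single-particle fluorescent bioaerosol
measurements (UV-LIF instruments of the WIBS-4 type), aimed at quantifying
primary biological aerosol particles (PBAP) carried in sea spray aerosol over
remote oceans — and at anyone who needs a tested, reusable implementation of
that analysis chain: threshold-based fluorescence tiering, ABC classification,
the R_B2A humification-index ratio, pristine-marine segregation of a ship
track, and the aerosol–seawater correlation statistics.  A synthetic campaign
generator with known ground truth makes the whole chain testable end to end
without access to any campaign's raw data.

## The model in brief

A WIBS-type instrument records, per particle, an optical diameter *d*, an
asymmetry factor AF, and fluorescence amplitudes FL_A, FL_B, FL_C in three
excitation/emission channels (A: 280 nm → 310–400 nm; B: 280 → 420–650;
C: 370 → 420–650).  Background "forced trigger" (FT) records define, per
channel *c*, thresholds

    T3_c = m_c + 3 s_c        (fluorescent tier)
    T9_c = m_c + 9 s_c        (hyper-fluorescent tier)

with m_c, s_c the FT mean and sample SD.  A particle is *fluorescent* when
FL_c > T3_c in at least one channel, *hyper-fluorescent* when FL_c > T9_c in
at least one channel (a subset of the fluorescent tier), and its ABC class
(A, B, C, AB, AC, BC, ABC) is the combination of above-threshold channels.
The approximate humification index is

    R_B2A = FL_B' / FL_A'

with sub-threshold amplitudes censored to the channel's FT mean.  Coarse
(*d* ≥ 1 µm) fluorescent number fractions and concentrations, computed in
half-open time bins as count/(flow × duration), are then segregated into
pristine-marine (> 200 km from any coastline, great-circle distance) and
terrestrially influenced samples, and correlated against sea-spray proxies
and seawater biology variables with Pearson R, a 100×60% subsampling
bootstrap and a two-sided permutation test (≥ 25 pairs required).

See `docs/methods.md` for the full account, including the synthetic
generator's calibration.

## Worked example

```python
import numpy as np
from pbapflow import (
    generate_campaign, get_preset, compute_ft_stats, classify_particles,
    compute_rb2a, class_fractions, time_binned_series,
)

campaign = generate_campaign(get_preset("pristine", duration_h=7 * 24.0, seed=11))
thresholds = compute_ft_stats(campaign.ft_records)
lab3 = classify_particles(campaign.particles, thresholds, 3)
lab9 = classify_particles(campaign.particles, thresholds, 9)
hourly = time_binned_series(
    campaign.particles, lab3["in_tier"].to_numpy(), lab9["in_tier"].to_numpy()
)

print(f"particles: {len(campaign.particles):,}")
print(f"3-sigma thresholds (A,B,C): {np.round(thresholds.t3, 2)}")
print(f"median fluorescent conc:  {hourly['conc_fluor'].median():.2f} L^-1")
print(f"median hyper conc:        {hourly['conc_hyper'].median():.2f} L^-1")
print(f"median fluorescent frac:  {100 * hourly['frac_fluor'].median():.2f} %")
print(f"median hyper frac:        {100 * hourly['frac_hyper'].median():.3f} %")
fracs = class_fractions(lab3)
print("ABC class fractions (3-sigma):")
print(fracs.round(3).to_string())
rb2a = compute_rb2a(campaign.particles, thresholds, 3)
print(f"median R_B2A of fluorescent particles: "
      f"{np.median(rb2a[lab3['in_tier']]):.2f}")
```

prints

```
particles: 2,393,333
3-sigma thresholds (A,B,C): [64.98 52.12 39.13]
median fluorescent conc:  11.01 L^-1
median hyper conc:        1.01 L^-1
median fluorescent frac:  1.68 %
median hyper frac:        0.136 %
ABC class fractions (3-sigma):
abc_class
A      0.263
B      0.328
AB     0.141
C      0.111
AC     0.005
BC     0.046
ABC    0.106
median R_B2A of fluorescent particles: 0.80
```

A one-week campaign recovers the preset's calibration — a 1.6% fluorescent
and 0.13% hyper-fluorescent coarse fraction, 11.4 L⁻¹ median fluorescent
concentration — to within weekly weather noise.  The per-particle tier
labels, the thresholds and the R_B2A values are all plain pandas/numpy
objects.

## Command line

The same stages are exposed as subcommands over documented CSV formats:

```sh
pbapflow simulate --preset pristine --seed 42 --out camp/
pbapflow classify --k 3 --ft camp/ft.csv --particles camp/particles.csv --out labels.csv
pbapflow aggregate --ft camp/ft.csv --particles camp/particles.csv --out hourly.csv
pbapflow segregate --track camp/track.csv --coastline camp/coastline.csv --out mask.csv
pbapflow scan-threshold --hourly hourly_with_distance.csv --grid 25:500:25 --out scan.csv
pbapflow correlate --marine camp/marine.csv --hourly hourly.csv --out corr.csv
pbapflow run --config config.yaml --out bundle/    # full pipeline, deterministic
```

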