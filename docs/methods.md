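# Methods

`pbapflow` implements the analysis chain for single-particle UV-LIF
(ultraviolet light-induced fluorescence) bioaerosol measurements of the
WIBS-4 type made from a ship over a remote ocean, together with a synthetic
campaign generator that makes every stage of the chain testable against known
ground truth.  This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not emulate.

## Instrument model and classification

Each detected particle carries an optical diameter `d` (µm), an asymmetry
factor `AF` (dimensionless shape proxy; ~spherical particles sit near the low
end), and fluorescence amplitudes in three channels:

| channel | excitation | emission band |
|---|---|---|
| A | 280 nm | 310–400 nm |
| B | 280 nm | 420–650 nm |
| C | 370 nm | 420–650 nm |

Detection thresholds come from forced-trigger (FT) records — background
acquisitions with no particle present.  With per-channel FT mean `m_c` and
sample standard deviation `s_c` (n−1 denominator; at least two records are
required), the fluorescent tier threshold is `m_c + 3 s_c` and the
hyper-fluorescent tier threshold is `m_c + 9 s_c`.  A channel is "on" when
its amplitude *strictly* exceeds the threshold; ties are classified off.  The
strict rule is a convention fixed for testability — amplitude ties are
measure-zero for continuous signals.  A particle is in a tier when at least
one channel is on at that tier's threshold, which makes the 9σ tier a subset
of the 3σ tier automatically.  The on/off pattern over (A, B, C) maps the
particle to one of the seven ABC classes (A, B, C, AB, AC, BC, ABC).

The approximate humification index is `R_B2A = FL_B' / FL_A'`, where the
primed amplitudes equal the measured ones when above the tier's own threshold
(3σ for the fluorescent analysis, 9σ for the hyper analysis) and are censored
to the channel's FT mean otherwise, so that detector noise cannot drive the
ratio.  `R_B2A` is invariant under a common rescaling of both channels
(amplitudes and FT statistics together); high values indicate humic-like,
low values protein-like fluorophores.

## Aggregation conventions

* Time bins are half-open, left-closed UTC intervals `[t, t+w)`; defaults are
  5 min for particle products and 1 h for correlation products.
* Number concentration is `count / (flow × duration)` with a default sample
  flow of 0.23 L min⁻¹ (instrument constant, configurable).
* The fine/coarse split is at `d = 1 µm`; the boundary particle counts as
  coarse.  All headline fractions are over coarse particles.
* The default size grid is 16 logarithmic bins from 0.5 to 16 µm (the upper
  edge is configurable; reported instrument ranges vary between 14 and
  16 µm).  Particles outside the grid are tallied as overflow, never silently
  dropped.
* Fractions of empty bins are reported as missing (NaN), never zero.
* Latitude binning uses 4° intervals anchored at multiples of 4°, half-open
  toward the pole; bins with fewer than a configurable minimum of samples are
  flagged.

## Geospatial segregation

Coastlines are densified vertex point clouds (spacing < 10 km); distance to
land is the minimum great-circle (haversine, Earth radius 6371 km) distance
over vertices.  At the 200-km scales of interest the densification error
(< 5 km) is negligible, which is why polygons are not needed.  A sample is
*pristine-marine* iff its distance to land strictly exceeds the threshold
(default 200 km); ties are terrestrial.

The threshold itself can be estimated from the data: for each candidate
threshold `t`, Pearson R is computed between hourly fluorescent concentration
and a sea-spray proxy (wind speed by default) over the subset with distance
> `t`.  The plateau estimate is the smallest `t` whose R differs by less than
`ε` (default 0.02) from R at *every* larger valid threshold; thresholds whose
subset has fewer than 25 pairs are excluded.  This ε-stability rule is this
package's formalisation of what is otherwise a visual judgement; `ε` is
configurable and results should be quoted together with the scan curve, since
an exponential-tailed contamination source has no sharp spatial cutoff and
the plateau location carries an intrinsic uncertainty of roughly one to two
grid steps (±25–50 km on a 25-km grid).

## Correlation machinery

Marine point samples are paired with the hourly aerosol average covering
their timestamp; samples in hours without aerosol data are dropped and
counted.  Fractions (not absolute concentrations) are the aerosol quantity
correlated against seawater variables, to suppress spurious cross-correlation
through wind and loss processes.  Results are only reportable with at least
25 pairs.  Uncertainty comes from a subsampling bootstrap: 100 replicates,
each recomputing R on a random 60% of pairs drawn *without* replacement
(subsampling, not a classical bootstrap — the replicate size is what the
procedure prescribes).  Significance comes from a two-sided permutation test,
`p = (1 + #{|r*| ≥ |r|}) / (1 + B)` with `B = 10 000` by default; the add-one
correction avoids `p = 0`.  The choice of two-sided and of `B` are this
package's defaults where the procedure leaves them open.  No multiple-testing
correction is applied across marine variables; p-values are reported raw.

Class-fraction robustness uses two subsampling modes over the table of
per-5-min ABC class fractions: 288 randomly drawn rows (the equivalent of
12 h of 5-min data), or a randomly placed fixed 24-h window required to
contain at least 12 h of data.

## The synthetic campaign generator

The generator's defaults *are* the study conditions; they are calibrated once
and not tuned per run.

**Particle stream.**  Arrivals are homogeneous Poisson within each 5-min bin
with rate `concentration × flow`.  Optical sizes follow a lognormal (median
1.3 µm, σ_log = 0.6) truncated to 0.5–16 µm; the coarse (>1 µm) part of the
stream has a median concentration of `base_coarse_conc`, which the `pristine`
preset sets to 712.5 L⁻¹ so that a 1.6% fluorescent fraction yields the
11.4 L⁻¹ median fluorescent concentration the analysis is calibrated to.
Wind speed is a stationary AR(1) process on the log scale (median 9 m s⁻¹,
σ_log = 0.35, autocorrelation time 24 h — the synoptic timescale; 90 days
then contain ~45 independent weather realisations, enough for campaign
medians to be meaningful).  Concentration couples to wind as
`(u/9)^1.5` with a small lognormal nugget.

**Fluorescent subpopulations.**  Each particle's probability of being a
fluorescent emitter rises with diameter along a logistic ramp in log d
(≈1–2% below 2 µm, saturating near 40% at the top of the size range);
the hyper-fluorescent ramp is centred at `hyper_size_mode_um` (5 µm) so the
hyper size distribution develops a coarse mode near 5–8 µm.  Both ramps are
rescaled by a deterministic numerical calibration at preset build time so
their means over the coarse size distribution equal `fluor_fraction` (1.6%)
and `hyper_fraction` (0.13%) exactly.  A slow AR(1) "biology" modulation
(σ_log = 0.35, τ = 24 h, median 1) multiplies both fractions in time; the
hyper and fluorescent modulations are correlated (ρ = 0.6).

**Amplitudes.**  Non-emitters draw background amplitudes from the FT noise
model clipped below the 3σ cutoff; fluorescent-only emitters draw their lit
channels from a lognormal truncated to the (3σ, 9σ) band and hyper emitters
above 9σ, each keeping a 0.5-SD guard away from the exact cutoffs.  The
consequence — intentional — is that detected tier equals ground-truth tier
even though the pipeline re-estimates thresholds from a finite FT sample.
This makes label-recovery exact and places all stochasticity in the emission
process, at the cost of not emulating near-threshold misclassification or
false positives from background fluctuation; passing recovery tests therefore
validate the pipeline mechanics and calibration, not threshold-noise
robustness on real data.  Lit-channel patterns are drawn from per-population
ABC class probability tables (protein-like A/B-heavy for the marine
populations, BC-heavy for the terrestrial one).

**Asymmetry factor.**  Lognormal around a size-dependent median: ≈5 below
2.5 µm, rising to 10–20 over 5–14 µm, mirroring the reported shape behaviour
of sea-spray-dominated streams.

**Terrestrial plume (mixed preset).**  An additional population is emitted at
rate `A · exp(−d_land/L)` with coastal amplitude `A = 250 L⁻¹`, e-folding
`L = 70 km`, lognormal intermittency (σ_log = 0.7, τ = 6 h) and a 50%
fluorescent probability.  The 60-day track stays ~700 km offshore except for
a sustained mid-campaign excursion oscillating between 100 and 250 km from a
meridional coast, with fast transit legs.  These values were chosen
analytically and verified so that the plume's influence on the
concentration–wind correlation dies out near 200 km — the condition the
distance-threshold scan is designed to detect; the excursion geometry keeps
the far-field subset essentially fixed across scan thresholds, so the plateau
detector is not confounded by subset-sampling drift.

**Seawater variables.**  Ten variables (bacterial counts, phytoplankton
taxa masses, organic-matter measures) are sampled every 3 h and coupled to
the latent fluorescent (bacteria-like) or hyper-fluorescent
(phytoplankton-like) modulation signals through a Gaussian copula with
per-variable correlation (0.1–0.69) and lognormal marginals.  Only the
correlation structure is meaningful; medians and units are placeholders on
realistic scales.

**What the generator does not emulate:** instrument coincidence and
counting-efficiency roll-off below 0.7 µm, amplitude saturation, detector
drift, ship-exhaust contamination structure (a flag-injection hook exists for
mask testing, but the flag is exact rather than inferred), air-mass history,
and any mechanistic sea-spray flux physics.  Tests passing on synthetic
campaigns demonstrate correctness of the analysis chain and its calibration
machinery, not fidelity of any geophysical conclusion.

## Problem sizes and determinism

The calibrated `pristine` preset spans 90 days and produces ≈3×10⁷ particles
(≈2×10⁷ coarse) at the default flow; it generates in about a minute and fits
comfortably in a few GB.  The `mixed` preset spans 60 days.  Unit tests use
2-day and 10-day campaigns.  Every random stage derives its generator from a
single seed through `numpy` `SeedSequence` spawning, so regeneration is
bit-identical and changing one stage's draws cannot silently shift another's.

## Known limitations

* The plateau estimate inherits ±1–2 grid steps of seed-to-seed variability;
  on the 25-km default grid individual runs occasionally land 75 km from the
  design value.
* CSV interchange stores microsecond-resolution timestamps; the generator
  rounds to that resolution so round trips are lossless.
* The quality-mask interface is pluggable but ships only with `pass_all` and
  a flag-bit mask; empirically derived exhaust masks must be registered by
  the user.
* Marine variables share a single pair of latent biology signals; real
  seawater variables have richer cross-correlation structure.
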