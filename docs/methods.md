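# Methods

`meaburst` quantifies treatment-induced inhibition of spontaneous
activity in cultured cortical networks recorded on planar microelectrode
arrays (MEAs). The pipeline mirrors a standard in-vitro exposure design:
30 min of baseline recording, 15 min of exposure (sham, an RF-field-like
treatment, or a muscimol-like GABA_A agonist), and 45 min of washout, on
60 channels digitized at 10 kHz. All analyses run per channel, pool over
the MEA, and express effects as exposure/baseline ratios.

## Synthetic activity model

No public raw data exist for this preparation, so the package ships a
generator whose output has the statistical structure the analysis
assumes. It is a doubly stochastic event-level model:

* **Network burst events.** Mature cultures burst collectively at
  quasi-regular intervals. Events are drawn from a gamma-renewal process
  with rate `network_burst_rate` (default 12/min) and regularity shape
  `burst_regularity` (default 4, i.e. inter-event CV = 0.5). Shape 1
  recovers a Poisson process. Each event recruits each channel with
  probability `burst_participation` (default 0.8) and a Gaussian
  cross-channel onset jitter (`onset_jitter_sd`, default 20 ms).
* **Isolated bursts.** Per-channel Poisson bursts are added so that a
  fraction `isolated_burst_fraction` (default 0.3) of each channel's
  bursts is single-channel; network bursts then make up 60-80 % of all
  bursts, the regime where collective bursting dominates the burst count.
* **Burst content.** Burst durations are log-normal
  (`burst_duration_mean` 0.3 s, CV 0.3); spikes inside a burst are a
  flat-rate Poisson at `intra_burst_rate` (80 spikes/s). No
  accommodation is modeled; the metric panel is insensitive to
  within-burst rate shape.
* **Background.** Out-of-burst tonic spiking is Poisson at
  `background_rate` (2 spikes/s). Per-channel log-normal rate
  multipliers (`channel_rate_heterogeneity`, CV 0.2) scale background
  and intra-burst rates.

Treatments are `EffectPreset`s: multiplicative changes applied during
exposure with an exponential onset transition (`onset_time_constant`,
30 s — activity collapses within the first exposure minute) and an
exponential post-washout recovery (`recovery_time_constant`, 300 s —
slow enough that washout alone produces no rebound-like overshoot in the
first post minutes). `burst_rate_scale` multiplies both network and
isolated burst rates, `background_rate_scale` the tonic rate,
`burst_duration_scale` and `intra_burst_rate_scale` the burst content.
`jitter_scale` models desynchronization: it scales the onset jitter and
divides the renewal shape by its square, so the muscimol-like value of 2
turns regular collective bursting Poisson-irregular during exposure
(raising the within-channel CV of inter-burst intervals, the synchrony
marker). A rebound flag multiplies the recovering network burst rate by
`rebound_magnitude` for `rebound_duration` seconds after exposure ends —
rebound is a property of collective bursting only, not of tonic spiking.

The built-in presets encode the three study arms. Their multipliers are
calibration constants chosen in closed form so that the *measured*
pipeline output — after burst detection and normalization, including the
onset transition (phase-averaged multiplier `s + (1-s)(tau/T)(1-e^(-T/tau))`)
— reproduces the reference effect sizes: ~35 % (RF-like) and ~57 %
(muscimol-like) reduction of the mean bursting rate, and ~14 % / ~58 %
reduction of out-of-burst spiking. The muscimol-like preset adds the
rebound (magnitude 2, 60 s) and stronger desynchronization; both active
presets narrow the rendered AP width to 93 %.

What the generator does **not** emulate: electrode noise correlations,
burst propagation structure and latency gradients across the array,
development or drift over the session, bursty single-unit refractoriness,
and any biophysics of the exposure itself (temperature, SAR dosimetry,
receptor kinetics). Passing tests therefore show that the analysis
recovers known effects embedded in data with this structure — not that
the effects exist in any real recording.

## Detection and burst extraction

* **Filtering.** 4th-order Butterworth high-pass at 70 Hz, applied
  forward-backward (zero phase). Noise is estimated per channel by the
  scaled median absolute deviation, `median(|x - median(x)|)/0.6745`,
  which ignores the sparse spikes riding on the noise.
* **Spike detection** uses a differential (peak-to-peak) threshold: a
  local trough is a spike when the excursion between it and the largest
  opposite extremum within the 2 ms peak lifetime period exceeds 8x the
  noise sd; spike time is the trough sample; events within 1 ms collapse
  onto the larger. The multiplier, lifetime and refractory are
  conventional values for this detector and are config-exposed.
* **Waveform path.** Independently of the detector above, snippets of
  40 samples (0.8 ms before the trough, 3.2 ms after, at 10 kHz) are cut
  for troughs exceeding 5x the noise sd, mirroring the two-tool split
  between rate analysis and AP-shape analysis.
* **Burst detection** is the logISI-histogram method: histogram of
  log10 inter-spike intervals (10 bins/decade, 3-bin moving average),
  intra-burst mode below a 100 ms cap, threshold at the minimum between
  that mode and the next slower mode when the void parameter
  `1 - h_min/sqrt(h1 h2)` reaches 0.7, else the 100 ms cap. Maximal runs
  of ISIs at or below threshold with >= 5 spikes are bursts. A
  single-threshold variant is used (no burst-core extension by a second
  threshold): detection stays deterministic and the panel is insensitive
  to sub-threshold edge spikes at these effect sizes. The intra-burst
  peak must additionally reach 10 % of the histogram maximum; without
  this floor, counting noise in the fast tail of a slow unimodal
  histogram can fabricate a sub-cap threshold.
* **Network-burst labeling** (onsets co-occurring within 100 ms on
  >= 20 % of active channels) validates the generator; the metric panel
  itself pools isolated and network bursts without distinction.

## Metric panel and normalizations

Active channels are those with both spiking (>= 0.02 spikes/s at
baseline) and bursting (>= 2 baseline bursts); the thresholds are
concrete choices for "showing both spiking and bursting activities".
Per channel and phase: MBR (bursts/min), IBI (mean end-to-next-start
gap; the gap definition keeps IBI and BD non-redundant, a flag can
switch to start-to-start), BD (s), IBSR (in-burst spikes / in-burst
time), MSR (out-of-burst spikes / out-of-burst time). Spikes are
attributed to burst intervals with closed bounds `[start, end]` so that
in-burst + out-of-burst equals the total exactly; all other windows are
half-open. MEA-level values are unweighted means over active channels.

Effects are fractional variations `R_M = M_exposure / M_baseline`,
computed at the pooled level (ratio of pooled means) and per channel;
zero baselines flag the ratio undefined and drop it from pooling.
Cross-channel synchrony is the coefficient of variation
`CV = 100 x mean_c(sd_c) / pooled mean` of burst-level metric values
(lower CV = tighter synchrony). Spatial variability of an effect is the
normalized RMSE `sqrt(sum_k (Y - y_k)^2 / K) / Y` of per-channel R
values around the MEA-level R: 0.5 means the mean inter-channel
deviation is 50 % of the mean.

Temporal descriptors come from minute-binned, baseline-normalized rate
courses (10 s bins for trace-style output): the initial inhibitory rate
is the OLS slope over the first five exposure minutes (fraction/min),
and the post-inhibitory rebound (PIR) is the maximum of the first two
post-washout minutes over the mean of the last five exposure minutes.
Both operationalizations are package choices (bin counts configurable):
the slope captures "collapse within the first minute" robustly, and the
two-minute PIR window brackets a ~1 min rebound regardless of its exact
phase within the bin grid.

## Waveform analysis

Snippets from merged baseline+exposure segments are sorted per channel:
projection onto the first three principal components, Gaussian mixtures
with 1-4 full-covariance components selected by BIC, and a Mahalanobis
outlier bound (squared distance beyond 1.5x the 0.99 chi-square
quantile leaves a spike unsorted). This is an open, deterministic
stand-in for proprietary T-distribution EM sorters; channels with fewer
than 20 snippets are skipped. Clusters rank by spike count into one MAJ
unit per channel, AUX units holding >= 15 % of sorted spikes, and MIN
units; only MAJ and AUX units enter the waveform statistics (they hold
>= 80 % of sorted spikes under generator defaults).

Features of the mean waveform (baseline = mean of the first four
samples): peak and anti-peak amplitude, trough FWHM by linear
interpolation of the half-level crossings, and the two edge slopes.
Because the extracellular AP is inverted, the *rising edge*
(depolarization equivalent) is the fastest pre-trough downstroke
magnitude, and the *falling edge* is the fastest trough-to-peak recovery
slope; this convention is fixed throughout the package. Exposure effects
are per-unit exposure/baseline ratios averaged over MAJ+AUX units.

## Dose-response and group statistics

Normalized MBR against dose follows a four-parameter logistic
`R(d) = floor + (ceiling - floor)/(1 + (d/d50)^h)`, fitted by bounded
least squares from five deterministic starts (d50 spread over the dose
range, Hill ladder 1-8). Concentration fits parameterize d50 on a log10
axis, SAR fits on a linear axis. The floor can be pinned (e.g. at 0 for
agonists, where saturating doses fully suppress activity — pinning also
removes the floor/d50 identifiability drift seen in small noisy panels);
by default it is free. Goodness of fit is a chi-square of residuals
standardized by replicate-pooled variance, df = points - free
parameters; exactly zero residuals short-circuit to statistic 0, p = 1.
The synthetic dose models place half-suppression at 0.25 uM (Hill 1.5)
for the agonist and 28.6 W/kg (Hill 8 — inhibition only above
~25 W/kg) for SAR, with 5 % multiplicative log-normal replicate noise
and the study's per-dose replicate counts.

Group comparisons are Kruskal-Wallis (ties-corrected, chi-square
reference) followed by Conover-Iman all-pairs tests on pooled ranks with
pooled variance and a Student-t reference, unadjusted by default (Holm
by flag); effect size is epsilon-squared `H/(n-1)`; the significance
pattern is rendered as compact letters via insert-and-absorb at
alpha = 0.05.

## Numerical and reproducibility choices

* All randomness flows from one integer seed; network-level and
  per-channel substreams derive from `SeedSequence([seed, channel])`,
  per-culture seeds from `(seed, arm_index, culture_index)`, kept below
  2^31. Same seed, byte-identical outputs.
* Inhomogeneous point processes are sampled by time rescaling on a
  0.25 s cumulative-rate grid (trapezoidal integration), which bounds
  rate-profile interpolation error well below sampling noise.
* Degenerate inputs: all-constant signals estimate noise 0 and detect
  nothing; channels with < 2 bursts have undefined IBI (excluded from
  that metric's pooling); zero baselines flag R undefined; GMM
  covariance failures fall back to a single cluster.
* Intervals defined by spikes (bursts) are closed; clock windows
  (phases, bins) are half-open `[t0, t1)`; indices are 0-based.

## Problem sizes

Study-scale runs (60 channels, 30/15/45 min, arms of 12 sham / 15
RF-like / 8 muscimol-like cultures) are used for the effect-size and
rebound analyses; a culture simulates and analyzes in a few seconds.
Unit and property tests run on reduced instances (10-16 channels,
10/5/10 min) that preserve the phase structure, and waveform-level
rendering uses short segments (2-8 channels, 1-5 min per phase) since
raw-voltage synthesis at 10 kHz dominates runtime. The acceptance script
uses the full study conditions for every pipeline-level quantity.

## Known limitations

* The generator's burst interior is flat-rate; IBSR-related synchrony
  statistics see less within-burst structure than real data.
* The PIR and initial-rate operationalizations are reasonable but not
  unique; alternative windows shift absolute values (comparisons between
  arms are robust to the choice).
* The sorter's cluster count is capped at 4 per channel and templates do
  not drift; real recordings show unit drift and overlap that the
  waveform path does not attempt to resolve (no overlapping-spike
  decomposition, no stimulus blanking).
* Whole-record batch processing only; no streaming.
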