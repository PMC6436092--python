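# Methods

`cdk2fluct` studies how stochastic replication stress shapes CDK2 activity
during S phase. Because no live-cell imaging data ship with the package, every
estimator is validated by *parameter recovery*: a generative model produces
traces and images whose ground truth is known, and the quantification chain
must read the configured parameters back out.

## The dip-sum trace model

CDK2 activity is reported as the cytoplasmic:nuclear ratio of a
translocation reporter. The model assumes:

- activity is zero in quiescence/early G1, then ramps linearly from the G1
  rise onset through G2 (`ramp_slope`, default 0.18 activity units/h; the ramp
  is written `ramp_offset + ramp_slope·(t − s_start)` floored at zero, so with
  the default offset of 0.54 the rise precedes S entry by 3 h);
- `n_events` stochastic replication-stress events (default 20) occur during S
  phase, each subtracting a Gaussian dip
  `α·exp(−(t − t_i)²/dip_shape)` from the ramp. With `α = 0.1` and
  `dip_shape = 0.5 h²` each dip is ~1 h wide at half-maximal suppression
  (FWHM `2√(dip_shape·ln 2) ≈ 1.18 h`) and removes `α√(π·dip_shape)`
  activity·hours from the trace. Dips superpose linearly and are not clipped
  at zero unless requested;
- the APC/C-substrate degron accumulates linearly (0.5 intensity/h) from
  APC/C inactivation, which trails the CDK2 rise by `degron_lag = 3 h`;
- Gaussian measurement noise (sd 0.02 ratio units) is added per frame to the
  ratio and degron series; frames are 12 min (0.2 h) apart.

The dip amplitude and the noise level are not constrained by any published
measurement; the defaults were chosen once to give trace fluctuations of the
magnitude seen in live-cell recordings of this reporter and are exposed in
`StressModelConfig`.

**Event placement.** `sample_stress_events` draws event times i.i.d.
uniformly over S phase — the plain Monte Carlo model. Regime presets instead
cluster events around quasi-periodic centers (`event_spacing`, with per-cell
random phase and Gaussian jitter): this endows the dip train with a dominant
fluctuation period while each cell's event times remain random, which is the
only way a population autocorrelation analysis can be given a known period to
recover. With uniform i.i.d. events the detrended autocorrelation has no
interior minimum to find.

**Regime presets.**

| parameter | cycling | quiescence_release |
|---|---|---|
| S duration | 6 h | 9 h |
| event count | 20 | 40 (2× burden) |
| event spacing (period) | 2.4 h | 1.6 h |
| dip shape | 0.5 h² | 0.25 h² |
| puncta burden (mean/nucleus) | 6 | 12 |

The cycling spacing of 2.4 h makes the population anticorrelation minimum
fall at 1.2 h. The quiescence-release preset is a phenomenological emulation
of cell-cycle re-entry after mitogen starvation: longer S phase, doubled
stress burden, and sub-hour anticorrelation lag. The sub-hour lag cannot be
produced with 1.2-h-wide dips — the dip autocovariance (a Gaussian of sd
`√(dip_shape/2)·√2`) blurs any periodicity shorter than about 2 h — so the
preset uses narrower dips (FWHM ≈ 0.83 h) with 1.6-h spacing, yielding a
0.8-h lag. The `0.5 h²` shape stays the default everywhere else.

**Washout scenario.** `simulate_washout` isolates an exogenous
polymerase-inhibitor pulse: endogenous dips are off; any non-zero dose stalls
the activity ramp at the last pre-drug frame (fork stalling saturates at the
doses modeled while the CDK2 drop is dose-proportional); during the pulse the
activity sits `suppression_fraction` below the pre-drug level, and after
washout the deficit decays exponentially with `recovery_halflife`
(default 40 min). A zero dose leaves the trace untouched.

**Synthesis-rate coupling.** `couple_synthesis_rate` attaches a relative DNA
synthesis rate `base·(1 + m·tanh(g·(a(t) − ā_S)))` during S phase (zero
outside), with modulation depth `m = 0.5`. The bounded form keeps the rate
strictly positive and boxcar-like across S phase — so the EdU-binning
duration estimator sees the full S span — while remaining strictly monotone
in instantaneous activity, which is what the pulse-chase correlation
analyses test. Pulse intensities (EdU/BrdU) are integrals of this rate over
the pulse window.

## The image model

Fields are rendered by inverting the measurement model: nuclei are disks of
radius 8 μm at 0.65 μm/px, the reporter channel carries the nuclear intensity
inside the disk and `ratio × nuclear` in a cytoplasm annulus extending 15 μm
beyond the nucleus (comfortably containing the 2–10 μm measurement ring), a
spatially constant background (100 counts) is added everywhere, and noise —
Poisson on the signal plus Gaussian read noise (sd 2) — is applied last.
Damage puncta are disjoint bright disks (default 0.65 μm, 200 counts) placed
uniformly inside the nucleus; the ground-truth puncta pixel count is the
rasterized union area.

What the renderer deliberately omits: cell motion and shape variation,
photobleaching, illumination gradients, mitosis, and autofluorescence
structure. Passing the round-trip tests therefore shows the measurement
chain is correct *given* its geometric assumptions, not that segmentation
would survive crowded or irregular real fields.

One bias is inherent to the measurement definition: the 75th percentile of a
noisy uniform cytoplasm sits ~0.67σ above its mean, so recovered ratios are
slightly high at low photon counts. The default rendering brightness
(nuclear reporter 1000 counts) keeps this below ~0.02 ratio units; it is a
property of the percentile estimator, not a bug in the renderer.

## The quantification chain

- **Segmentation**: Otsu threshold on the log-transformed smoothed nuclear
  channel, hole filling, distance-transform watershed declumping (markers
  from smoothed distance-map peaks), area gating. Deterministic.
- **Background**: nuclear masks dilated by 50 μm (distance-transform
  equivalent); the median of the remaining pixels is the per-channel global
  background. Dense synthetic layouts pass a smaller dilation explicitly.
- **Ring measurement**: the perinuclear ring is every background pixel whose
  distance to the cell's nuclear mask lies in (2, 10] μm, excluding pixels
  within 10 μm of any other nucleus. The cytoplasmic value is the 75th
  percentile (linear interpolation between order statistics) of
  strictly-positive background-subtracted ring pixels; the nuclear value is
  the median over the mask; their quotient is the activity ratio. Cells with
  no above-background ring pixel get a flagged, undefined ratio.
- **Puncta**: white top-hat with a circular element of radius 4 μm, absolute
  threshold (default: median + 5 robust SD of the filtered image), pixel
  count inside the nuclear mask. μm radii round to the nearest integer pixel.
- **Tracking**: greedy mutual-nearest-centroid linking with a 20 μm/frame
  displacement gate; unmatched detections open new tracks, ambiguous moves
  terminate tracks rather than guess.

## Trace statistics

- **Smoothing**: centered 3-frame moving mean, truncated at the ends.
- **QC**: cells in the bottom 5% of mean total reporter intensity are
  removed (boundary ties kept); traces with any frame-to-frame ratio jump
  above 0.25 are removed as noisy.
- **Landmarks**: the CDK2 rise is the first sustained (3-frame) excursion of
  the smoothed ratio above baseline + 0.1 (baseline = 10th percentile of the
  first 5 h); APC/C inactivation is the first sustained rise of the degron
  above 5% of its trace maximum. Both raw crossings are refined by fitting a
  line to the following hour and back-extrapolating to the baseline level —
  a threshold crossing on a ramp is systematically late by
  `threshold/slope`, and the refinement removes that bias (noise-free calls
  land within 2 frames of truth; the cohort rise→APC lag recovers 3 h).
- **Fluctuation score**: squared residual from a per-cell cubic fit starting
  at the alignment event; the window is truncated (and the cubic refit once)
  at the first frame where the fit exceeds 1.3, where reporter saturation
  makes ratios noisy. Adding any cubic to a trace leaves the score unchanged;
  a sinusoid of amplitude a scores a²/2. A second, fit-free score — the
  squared central second difference scaled by `Δt⁻⁴` — is used only for rank
  concordance, since its absolute scale weighs high frequencies differently.
- **Population profile**: mean, SEM (sd/√n) and n per aligned timepoint;
  timepoints with fewer than 2 cells are suppressed.
- **S-phase slope**: least-squares slope from S entry to the first frame at
  or above ratio 1.5; never-crossing cells are excluded, not extrapolated.
- **Drug response**: percent change from the last pre-drug frame to +1 h;
  recovery time is the interpolated first post-washout time at half the
  pre-drug level; the recovery half-life is a log-linear fit to the
  positive deficit within a fixed 1-h post-washout window. The fixed window
  matters: selecting fit frames by their own noisy deficit value biases the
  slope (~+9% on the half-life); the fixed window is unbiased (median
  recovery 39.9/40 min over 200 noisy cells).
- **Autocorrelation**: per-cell S-phase segments are cubic-detrended (the
  ramp would otherwise mask the oscillation), the biased ACF estimate is
  normalized at lag 0 and averaged over cells; the anticorrelation lag is
  the profile minimum in (0, max_lag]. Segments shorter than
  max_lag + 5 frames are skipped; the biased estimator keeps under-sampled
  long lags shrunk toward zero, which is why a 4-h max lag is usable on a
  6-h S phase.

## Population analyses

- **Pulse-chase rates**: cells positive for both stains (Otsu gate on log
  intensities by default; synthetic all-S-phase populations pass absolute
  thresholds) are ranked; a cell's incorporation rate is its mean-rank
  (Hazen) percentile, `100·(r − 0.5)/n` — invariant under monotone intensity
  transforms. `Δrate = BrdU rate − EdU rate`; `ΔCDK2` is the ratio change
  between pulse midpoints.
- **Binning**: Δrate binned by ΔCDK2 into 7 half-open bins from −0.10 to
  0.25 (step 0.05, values outside excluded); bin medians ± SEM; r² from an
  unweighted line through (bin center, median). Bin-level rather than
  cell-level regression, since the reported quantity is the bin median.
- **S-phase duration**: median EdU per 1-h bin of time since APC/C
  inactivation, curve rescaled to unit area (making the estimate invariant
  to global stain scaling), duration = span of the contiguous
  above-threshold run containing the curve maximum, threshold 25% of the
  curve peak.
- **Statistics**: time series are compared per timepoint by two-sided
  Mann-Whitney U with Bonferroni correction (m = timepoints actually
  tested). Column data use Shapiro-Wilk at α = 0.05 per group to choose
  between t-test / one-way ANOVA + Tukey HSD and Mann-Whitney / 
  Kruskal-Wallis + Dunn (Bonferroni); zero-variance groups force the rank
  branch. Dunn's z-tests on pooled mean ranks (with tie correction) are
  implemented in-package.

## Problem sizes and determinism

The recovery studies run at: washout half-life n = 200 cells, landmark lag
n = 500, anticorrelation lag n = 300, S durations n = 2000 per regime, and
the puncta contrast at 500 rendered nuclei per regime (fields of 25 nuclei,
60 μm pitch). All randomness flows from one root seed through
`numpy.random.SeedSequence` spawning (one child stream per cell, indexed
spawn for sub-studies), so every simulation, rendering and scenario output
is bit-for-bit reproducible under a fixed seed and independent of iteration
order.

## Known limitations

- Dips are phenomenological; there is no mechanistic checkpoint-signaling
  model, no mitosis, and no daughter-cell lineage.
- The renderer's stationary, circular cells make tracking trivially easy;
  the tracker's gate logic is exercised by constructed fixtures instead.
- The degron model is linear without saturation or degradation at mitosis.
- The second-derivative fluctuation score's normalization is a convention;
  only its ranking behavior is validated against the polynomial score.
- The quiescence-release preset encodes target phenomenology (durations,
  lags, burdens); recovering those values validates the estimators, not the
  biology that produced them.
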