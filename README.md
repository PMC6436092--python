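# cdk2fluct

Simulation and quantification of fluctuating CDK2 activity during S phase.

Single-cell imaging with a CDK2 translocation reporter (a DNA-helicase-B
fragment that leaves the nucleus when phosphorylated) shows that CDK2
activity does not rise smoothly through S phase: it fluctuates, dipping
transiently whenever replication stress activates ATR signaling. This
package implements, as a tested pipeline, both sides of that analysis:

- a **stochastic trace simulator** — CDK2 activity as a linear ramp minus a
  Monte Carlo sum of Gaussian suppression dips,

  `CDK2(t) = CDK2_linear(t) − Σᵢ α·exp(−(t − tᵢ)²/0.5)`,

  with 20 events per S phase, ~1-h-wide dips, a degron reporter marking
  APC/C<sup>Cdh1</sup> inactivation 3 h after the CDK2 rise,
  drug-pulse/washout kinetics, synthesis-rate coupling, and presets for
  continuously cycling vs quiescence-released cells;
- a **synthetic microscopy renderer** producing multi-channel fields
  (nuclear marker, reporter partitioning that encodes a prescribed
  cytoplasmic:nuclear ratio, degron, damage puncta) with full ground truth;
- the **quantification chain**: nuclear segmentation, global background
  estimation, perinuclear-ring measurement (2–10 μm outside the nucleus,
  neighbor-excluded; ratio = ring 75th percentile / nuclear median),
  top-hat puncta counting, centroid tracking;
- **trace and population statistics**: 3-point smoothing, QC gates,
  landmark calling, cubic-residual and second-derivative fluctuation
  scores, S-phase slope, percent change and recovery half-life,
  autocorrelation lag, EdU/BrdU percentile-rank pulse-chase analysis,
  AUC-normalized S-duration estimation, and the Mann-Whitney/Bonferroni
  testing conventions.

Since no real imaging data are bundled, every estimator is validated by
parameter recovery against the generators' stored ground truth.
See `docs/methods.md` for the model and all numerical conventions.

## Worked example

Simulate a cycling population, call the cell-cycle landmarks, and measure
the oscillation lag:

```python
import numpy as np
from cdk2fluct.synth_traces import simulate_population
from cdk2fluct import trace_analysis as ta

cells = simulate_population(regime="cycling", n_cells=300, seed=1)
lags = []
for c in cells:
    rise = ta.call_cdk2_rise(ta.smooth_trace(c.trace))
    apc = ta.call_apc_inactivation(c.trace)
    if rise is not None and apc is not None:
        lags.append(apc - rise)
print(f"mean rise->APC lag: {np.mean(lags):.2f} h")

windows = [(c.true_apc_inactivation, c.true_s_end) for c in cells]
_, _, lag = ta.autocorrelation_profile([c.trace for c in cells], windows)
print(f"anticorrelation lag: {lag:.1f} h")
```

prints

```
mean rise->APC lag: 3.10 h
anticorrelation lag: 1.2 h
```

— the landmark callers recover the configured 3-h G1 ramp between CDK2
rise and S entry, and the autocorrelation minimum at 1.2 h reflects the
cycling preset's 2.4-h dip period (fluctuations recur every ~2.4 h, so a
trace is most unlike itself half a period later).

The numbered drivers under `analysis/` run the full studies and write
their tables under `results/`:

| script | what it shows |
|---|---|
| `01_simulate_traces.py` | trace populations + ground-truth sidecars |
| `02_image_roundtrip.py` | pixels→traces round trip (ratio MAE ≈ 0.01) |
| `03_fluctuation_metrics.py` | stressed vs dip-free fluctuation profiles and S-phase slopes |
| `04_washout_dose_response.py` | dose-ordered suppression, ~40-min recovery half-life |
| `05_nucleotide_pulse_chase.py` | ΔCDK2 vs Δincorporation-rate coupling (Spearman ≈ 0.95) |
| `06_regime_comparison.py` | 6 vs 9 h S phase, 1.2 vs 0.8 h lag, 2-fold puncta burden |

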