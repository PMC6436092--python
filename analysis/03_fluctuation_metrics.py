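#!/usr/bin/env python
"""Quantify S-phase CDK2 fluctuations: landmark calls, polynomial-residual
profiles for stressed vs dip-free populations, and S-phase slopes.

The dip-free population plays the role of the measurement-noise control:
its fluctuation profile stays flat after S entry while the stressed
profile rises, and its S-phase slope distribution sits above the
stressed one.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from cdk2fluct import trace_analysis as ta
from cdk2fluct.config import StressModelConfig
from cdk2fluct.synth_traces import simulate_population

SEED = 3
N = 200
out = Path("results")
out.mkdir(exist_ok=True)

cfg = StressModelConfig(ramp_slope=0.22, ramp_offset=0.66)
populations = {
    "stressed": simulate_population(cfg, n_cells=N, seed=SEED),
    "dip_free": simulate_population(cfg.replace(n_events=0), n_cells=N, seed=SEED),
}

profiles = {}
slopes = {}
for name, cells in populations.items():
    series, slp = [], []
    for c in cells:
        sm = ta.smooth_trace(c.trace)
        rise = ta.call_cdk2_rise(sm)
        apc = ta.call_apc_inactivation(c.trace)
        if rise is None:
            continue
        series.append(ta.fluctuation_polyfit(sm, rise))
        if apc is not None:
            s = ta.s_phase_slope(sm, apc)
            if s is not None:
                slp.append(s)
    prof = ta.population_profile(series)
    profiles[name] = prof
    slopes[name] = slp
    pd.DataFrame(
        {
            "aligned_time": prof.aligned_time,
            "mean_sq_dev": prof.mean_sq_dev,
            "sem": prof.sem,
            "n": prof.n,
        }
    ).to_csv(out / f"fluctuation_profile_{name}.csv", index=False)

for name, prof in profiles.items():
    late = prof.aligned_time >= 3.0
    print(
        f"{name}: mean squared deviation after S entry "
        f"{np.mean(prof.mean_sq_dev[late]):.2e} (n cells ~{prof.n.max()})"
    )
mwu = stats.mannwhitneyu(
    slopes["dip_free"], slopes["stressed"], alternative="greater"
)
print(
    f"S-phase slope: dip-free median {np.median(slopes['dip_free']):.3f}/h vs "
    f"stressed {np.median(slopes['stressed']):.3f}/h (one-sided p={mwu.pvalue:.2e})"
)
pd.DataFrame(
    [
        {"population": k, "median_slope": np.median(v), "n": len(v)}
        for k, v in slopes.items()
    ]
).to_csv(out / "s_phase_slopes.csv", index=False)
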