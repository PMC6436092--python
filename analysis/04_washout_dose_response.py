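#!/usr/bin/env python
"""Drug-pulse/washout dose series: percent change and recovery kinetics.

Simulates a 1-h suppression pulse at four doses, measures the activity
drop 1 h after drug addition and the post-washout recovery half-life,
and writes the dose-response table.
"""

import pandas as pd

from cdk2fluct.population_pipeline import run_experiment

out = run_experiment(
    {
        "scenario": "washout",
        "seed": 2,
        "n_cells": 150,
        "suppression_fractions": [0.1, 0.2, 0.3, 0.5],
    },
    "results/washout",
)
table = pd.read_csv(out / "washout_dose_response.csv")
print(table.to_string(index=False))
print(
    "\npercent change tracks the dose; the recovery half-life is "
    "dose-independent by construction (~40 min)."
)
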