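"""Parameter-recovery studies at the configurations the estimators target.

Each function generates synthetic data at the model's stated operating
point, runs the corresponding estimator from this package, and returns
the recovered quantity; they are shared by the acceptance script and the
acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from .config import WashoutProtocol, preset
from .synth_traces import couple_synthesis_rate, simulate_population, simulate_washout
from . import population_pipeline as pp
from . import trace_analysis as ta

__all__ = [
    "derive_seed",
    "washout_halflife",
    "landmark_lag",
    "anticorrelation_lag",
    "s_duration",
    "h2ax_contrast",
]


def derive_seed(root: int, index: int) -> int:
    """Independent 31-bit child seed for study ``index`` of a run."""
    return int(np.random.SeedSequence([root, index]).generate_state(1)[0] % 2**31)


def washout_halflife(
    seed: int, n_cells: int = 200, protocol: WashoutProtocol | None = None
) -> float:
    """Median fitted recovery half-life (min) over a washout population."""
    protocol = protocol or WashoutProtocol()
    cells = simulate_washout(preset("cycling"), protocol, n_cells, seed=seed)
    halflives = [
        ta.recovery_metrics(c.trace, protocol.t_add, protocol.t_washout).halflife
        for c in cells
    ]
    return float(np.median([h for h in halflives if h is not None]))


def landmark_lag(seed: int, n_cells: int = 500) -> float:
    """Mean called CDK2-rise to APC/C-inactivation lag (h), cycling preset."""
    cells = simulate_population(regime="cycling", n_cells=n_cells, seed=seed)
    lags = []
    for c in cells:
        rise = ta.call_cdk2_rise(ta.smooth_trace(c.trace))
        apc = ta.call_apc_inactivation(c.trace)
        if rise is not None and apc is not None:
            lags.append(apc - rise)
    return float(np.mean(lags))


def anticorrelation_lag(
    seed: int, n_cells: int = 300, regime: str = "cycling", max_lag: float = 4.0
) -> float:
    """Lag (h) of maximum anticorrelation of detrended S-phase traces."""
    cells = simulate_population(regime=regime, n_cells=n_cells, seed=seed)
    windows = [(c.true_apc_inactivation, c.true_s_end) for c in cells]
    _, _, lag = ta.autocorrelation_profile(
        [c.trace for c in cells], windows, max_lag=max_lag
    )
    return float(lag)


def s_duration(seed: int, regime: str, n_cells: int = 2000) -> float:
    """S-phase duration (h) from the AUC-normalized EdU binning estimator."""
    cells = simulate_population(regime=regime, n_cells=n_cells, seed=seed)
    coupled = [couple_synthesis_rate(c, 1.0) for c in cells]
    stream = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    tc = pp.edu_timecourse(coupled, stream=stream)
    duration, _ = pp.s_phase_duration(
        tc["time_since_apc"].to_numpy(), tc["edu"].to_numpy()
    )
    return float(duration)


def h2ax_contrast(seed: int, n_cells: int = 500) -> tuple[float, float]:
    """(QR/cycling median puncta-pixel ratio, comparison p-value)."""
    cy = pp.puncta_experiment(
        n_cells, preset("cycling").puncta_burden, seed=derive_seed(seed, 31)
    )
    qr = pp.puncta_experiment(
        n_cells,
        preset("quiescence_release").puncta_burden,
        seed=derive_seed(seed, 32),
    )
    ratio = float(np.median(qr) / np.median(cy))
    res = pp.compare_groups({"cycling": cy, "quiescence_release": qr})
    return ratio, float(res.pvalue)
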