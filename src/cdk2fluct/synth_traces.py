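"""Stochastic replication-stress trace simulator.

CDK2 activity is modeled as a linear ramp minus a sum of Gaussian
suppression dips centered at stochastic stress-event times in S phase:

    a(t) = max(0, ramp)  -  sum_i  alpha * exp(-(t - t_i)^2 / dip_shape)

with ``dip_shape = 0.5 h^2`` giving each dip a full width at half-maximal
suppression of ``2*sqrt(0.5*ln 2) ~ 1.18 h``.  A degron reporter rises
linearly after APC/C inactivation, which trails the CDK2 rise by
``degron_lag`` hours.  Populations carry full ground truth so every
downstream estimator can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import StressModelConfig, WashoutProtocol, preset
from .traces import CellTrace

__all__ = [
    "StressEvent",
    "SimulatedCell",
    "frame_grid",
    "sample_stress_events",
    "cdk2_baseline",
    "apply_stress_dips",
    "simulate_cell",
    "simulate_population",
    "simulate_washout",
    "couple_synthesis_rate",
    "integrate_rate",
]


@dataclass(frozen=True)
class StressEvent:
    """A single replication-stress event at center time ``t_i`` (h)."""

    t_i: float


@dataclass
class SimulatedCell:
    """A simulated cell: trace plus the ground truth that generated it."""

    trace: CellTrace
    true_events: list[StressEvent]
    true_cdk2_rise: float
    true_apc_inactivation: float
    true_s_duration: float
    true_activity: np.ndarray  # noise-free ratio on the frame grid
    true_synthesis_rate: np.ndarray | None = None
    true_recovery_halflife: float | None = None  # min
    protocol: WashoutProtocol | None = None
    regime: str | None = None

    @property
    def true_s_end(self) -> float:
        return self.true_apc_inactivation + self.true_s_duration


def frame_grid(config: StressModelConfig) -> np.ndarray:
    """Regular acquisition time grid from 0 to ``trace_end`` (inclusive)."""
    n = int(round(config.trace_end / config.frame_interval)) + 1
    return np.arange(n) * config.frame_interval


def sample_stress_events(
    config: StressModelConfig,
    stream: np.random.Generator,
    s_start: float | None = None,
    s_end: float | None = None,
) -> list[StressEvent]:
    """Draw the stress-event times for one S phase.

    With ``event_spacing=None`` the ``n_events`` times are i.i.d. uniform
    on ``[s_start, s_end]``.  With a spacing, events cluster (Gaussian
    jitter ``event_jitter_sd``) around quasi-periodic centers whose
    period is the spacing and whose phase is uniform per cell, which
    endows the dip train with that dominant period while keeping event
    times random across cells.
    """
    lo = config.s_start if s_start is None else s_start
    hi = config.s_end if s_end is None else s_end
    n = config.n_events
    if n == 0:
        return []
    if config.event_spacing is None:
        times = stream.uniform(lo, hi, size=n)
    else:
        spacing = float(config.event_spacing)
        phase = stream.uniform(0.0, spacing)
        centers = np.arange(lo + phase, hi + 1e-9, spacing)
        if len(centers) == 0:
            centers = np.array([lo + phase])
        picks = stream.integers(0, len(centers), size=n)
        times = centers[picks] + stream.normal(0.0, config.event_jitter_sd, size=n)
        times = np.clip(times, lo, hi)
    return [StressEvent(float(t)) for t in times]


def cdk2_baseline(t, config: StressModelConfig, s_start: float | None = None):
    """Dip-free CDK2 activity: zero in G0, then a linear ramp.

    The ramp is ``ramp_offset + ramp_slope * (t - s_start)`` floored at
    zero, so activity leaves zero at the G1 rise onset
    ``s_start - ramp_offset/ramp_slope`` and is continuous there.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > config.trace_end + 1e-9):
        raise ValueError("t outside the trace domain [0, trace_end]")
    s0 = config.s_start if s_start is None else s_start
    ramp = config.ramp_offset + config.ramp_slope * (t - s0)
    return np.maximum(ramp, 0.0)


def apply_stress_dips(
    baseline: np.ndarray,
    events: list[StressEvent],
    config: StressModelConfig,
    time: np.ndarray | None = None,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Subtract the Gaussian dip of each stress event from the baseline.

    Dips superpose linearly; the result is not floored at zero unless
    ``config.clip_at_zero`` is set.
    """
    t = frame_grid(config) if time is None else np.asarray(time, dtype=float)
    out = np.asarray(baseline, dtype=float).copy()
    if amplitudes is None:
        amplitudes = np.full(len(events), config.amplitude)
    for ev, amp in zip(events, amplitudes):
        out -= amp * np.exp(-((t - ev.t_i) ** 2) / config.dip_shape)
    if config.clip_at_zero:
        out = np.maximum(out, 0.0)
    return out


def _event_amplitudes(config: StressModelConfig, n: int, stream) -> np.ndarray:
    if config.amplitude_sd > 0:
        return np.maximum(
            stream.normal(config.amplitude, config.amplitude_sd, size=n), 0.0
        )
    return np.full(n, config.amplitude)


def simulate_cell(
    config: StressModelConfig,
    stream: np.random.Generator,
    cell_id: int = 0,
    regime: str | None = None,
) -> SimulatedCell:
    """Simulate a single cell on the global frame grid.

    The whole cell-cycle template is rigidly jittered in time by a
    per-cell N(0, ``rise_jitter_sd``) shift; stress events are sampled
    within the cell's own S window, dips and degron accumulation follow,
    and Gaussian measurement noise is added last.
    """
    t = frame_grid(config)
    delta = stream.normal(0.0, config.rise_jitter_sd) if config.rise_jitter_sd else 0.0
    # keep the shifted template inside the trace domain
    delta = float(np.clip(delta, -config.s_start + config.g0_end, 2.0))
    s_start = config.s_start + delta
    s_end = config.s_end + delta
    rise = s_start - (
        config.ramp_offset / config.ramp_slope if config.ramp_slope else 0.0
    )

    baseline = cdk2_baseline(t, config, s_start=s_start)
    events = sample_stress_events(config, stream, s_start=s_start, s_end=s_end)
    amps = _event_amplitudes(config, len(events), stream)
    activity = apply_stress_dips(baseline, events, config, time=t, amplitudes=amps)

    degron_true = np.where(t >= s_start, config.degron_slope * (t - s_start), 0.0)

    ratio = activity + stream.normal(0.0, config.noise_sd, size=len(t))
    degron = degron_true + stream.normal(0.0, config.noise_sd, size=len(t))

    nuc = np.ones_like(t)
    trace = CellTrace(
        cell_id=cell_id, time=t, ratio=ratio, nuc=nuc, cyto=ratio * nuc, degron=degron
    )
    return SimulatedCell(
        trace=trace,
        true_events=events,
        true_cdk2_rise=float(rise),
        true_apc_inactivation=float(s_start),
        true_s_duration=float(s_end - s_start),
        true_activity=activity,
        regime=regime,
    )


def _substreams(seed: int | None, n: int) -> list[np.random.Generator]:
    # one root SeedSequence; per-cell child streams by spawn index, so the
    # population is reproducible under any iteration order
    root = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in root.spawn(n)]


def simulate_population(
    config: StressModelConfig | None = None,
    n_cells: int = 100,
    regime: str | None = None,
    seed: int | None = 0,
) -> list[SimulatedCell]:
    """Simulate a population of cells under a config or a regime preset.

    Exactly one of ``config``/``regime`` is usually given; a regime name
    selects its preset (``cycling``: 6-h S phase, 2.4-h fluctuation
    period; ``quiescence_release``: 9-h S phase, 1.6-h period, doubled
    stress burden).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if config is None:
        config = preset(regime if regime is not None else "cycling")
    elif regime is not None:
        preset(regime)  # validate the name even when config overrides it
    streams = _substreams(seed, n_cells)
    return [
        simulate_cell(config, streams[i], cell_id=i, regime=regime)
        for i in range(n_cells)
    ]


def simulate_washout(
    config: StressModelConfig,
    protocol: WashoutProtocol,
    n_cells: int,
    seed: int | None = 0,
) -> list[SimulatedCell]:
    """Simulate a drug-pulse/washout experiment.

    The scenario isolates the exogenous perturbation: endogenous stress
    dips are off, and any non-zero dose stalls the activity ramp at the
    last pre-drug frame (fork stalling saturates at these doses while
    the CDK2 drop is dose-proportional).  During the pulse the activity
    drops by ``suppression_fraction`` of that pre-pulse level; after
    washout the deficit decays exponentially with the protocol
    half-life.  A zero suppression fraction leaves the trace
    unperturbed.
    """
    if not (0 <= protocol.t_add and protocol.t_washout <= config.trace_end):
        raise ValueError("protocol window outside the trace domain")
    cfg = config.replace(n_events=0)
    t = frame_grid(cfg)
    t_freeze = protocol.t_add - cfg.frame_interval
    hl_h = protocol.recovery_halflife / 60.0
    streams = _substreams(seed, n_cells)
    out = []
    for i, stream in enumerate(streams):
        cell = simulate_cell(cfg, stream, cell_id=i)
        s_start = cell.true_apc_inactivation
        stalled = protocol.suppression_fraction > 0
        u = cdk2_baseline(
            np.minimum(t, t_freeze) if stalled else t, cfg, s_start=s_start
        )
        pre = float(cdk2_baseline(np.array([t_freeze]), cfg, s_start=s_start)[0])
        deficit = np.zeros_like(t)
        in_pulse = (t >= protocol.t_add) & (t < protocol.t_washout)
        deficit[in_pulse] = protocol.suppression_fraction * pre
        after = t >= protocol.t_washout
        deficit[after] = (
            protocol.suppression_fraction
            * pre
            * 2.0 ** (-(t[after] - protocol.t_washout) / hl_h)
        )
        activity = u - deficit
        ratio = activity + stream.normal(0.0, cfg.noise_sd, size=len(t))
        trace = replace(
            cell.trace, ratio=ratio, cyto=ratio * cell.trace.nuc
        )
        out.append(
            replace(
                cell,
                trace=trace,
                true_activity=activity,
                true_recovery_halflife=protocol.recovery_halflife,
                protocol=protocol,
            )
        )
    return out


def couple_synthesis_rate(
    cell: SimulatedCell,
    coupling_gain: float,
    base_rate: float = 1.0,
    modulation: float = 0.5,
) -> SimulatedCell:
    """Attach a DNA-synthesis-rate series coupled to CDK2 activity.

    During S phase (APC/C inactivation to S end) the relative rate is
    ``base_rate * (1 + modulation * tanh(gain * (a(t) - a_ref)))`` with
    ``a(t)`` the noise-free activity and ``a_ref`` its S-phase mean:
    monotone increasing in instantaneous activity, constant at gain 0,
    zero outside S phase, and bounded so activity excursions modulate
    rather than dominate the rate (modulation < 1 keeps it positive).
    """
    t = cell.trace.time
    in_s = (t >= cell.true_apc_inactivation) & (t <= cell.true_s_end)
    rate = np.zeros_like(t)
    if np.any(in_s):
        a = cell.true_activity
        a_ref = float(np.mean(a[in_s]))
        rate[in_s] = base_rate * (
            1.0 + modulation * np.tanh(coupling_gain * (a[in_s] - a_ref))
        )
    return replace(cell, true_synthesis_rate=rate)


def integrate_rate(cell: SimulatedCell, t0: float, t1: float, n_sub: int = 20) -> float:
    """Integral of the synthesis rate over ``[t0, t1]`` (pulse intensity).

    The stored per-frame rate is linearly interpolated; outside the trace
    domain the rate is zero.
    """
    if cell.true_synthesis_rate is None:
        raise ValueError("cell has no synthesis rate; call couple_synthesis_rate")
    if t1 <= t0:
        return 0.0
    tt = np.linspace(t0, t1, n_sub)
    rr = np.interp(tt, cell.trace.time, cell.true_synthesis_rate, left=0.0, right=0.0)
    return float(np.trapezoid(rr, tt))
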