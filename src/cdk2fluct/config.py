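"""Model configuration for the stochastic replication-stress trace simulator.

The simulated quantity is the cytoplasmic:nuclear ratio of a CDK2
translocation reporter ("activity units").  A cell's activity is zero in
quiescence, ramps linearly from the G1 rise onset through the end of the
trace, and is transiently suppressed during S phase by Gaussian-shaped
dips representing stochastic replication-stress events.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class StressModelConfig:
    """Parameters of the dip-sum model of fluctuating CDK2 activity.

    Times are hours on a per-cell template clock; individual cells are
    jittered rigidly in time when a population is simulated.

    Parameters
    ----------
    g0_end : h
        End of quiescence; activity is identically zero before the ramp
        onset, which must not precede this point.
    s_start, s_end : h
        S-phase entry (APC/C inactivation) and exit.
    trace_end : h
        Last simulated time point.
    ramp_slope : activity units / h
        Slope of the linear activity ramp.
    ramp_offset : activity units
        Ramp value at ``s_start``.  The ramp onset (CDK2 rise) is the
        zero crossing ``s_start - ramp_offset / ramp_slope``; with the
        defaults that places the rise 3 h before S entry.
    n_events : int
        Number of stress events per S phase (20 by default).
    amplitude : activity units
        Dip depth alpha, identical for every event unless
        ``amplitude_sd`` > 0.
    dip_shape : h^2
        Denominator of the squared-time term of each Gaussian dip; 0.5
        gives a full width at half-maximal suppression of about 1 h.
    event_spacing : h or None
        None draws event times i.i.d. uniformly over S phase.  A value
        clusters events around quasi-periodic centers with that period,
        encoding the regime's dominant fluctuation period.
    event_jitter_sd : h
        Gaussian jitter of clustered event times around their center.
    degron_lag : h
        Delay from CDK2 rise to APC/C inactivation, i.e. to the onset of
        degron-reporter accumulation.
    degron_slope : intensity units / h
        Linear accumulation rate of the degron reporter after APC/C
        inactivation.
    noise_sd : activity units
        Additive Gaussian measurement noise per frame, applied to the
        ratio and (in intensity units) to the degron signal.
    frame_interval : h
        Sampling interval (0.2 h = 12 min).
    rise_jitter_sd : h
        Per-cell Gaussian jitter of the whole cell-cycle template.
    puncta_burden : mean count
        Mean number of nuclear damage puncta per cell handed to the
        image renderer for fixed-cell scenes.
    clip_at_zero : bool
        Floor the dip-summed activity at zero (off by default; the model
        is an unclipped sum).
    amplitude_sd : activity units
        Optional spread of per-event amplitudes (off by default).
    """

    g0_end: float = 2.0
    s_start: float = 8.0
    s_end: float = 14.0
    trace_end: float = 17.0
    ramp_slope: float = 0.18
    ramp_offset: float = 0.54
    n_events: int = 20
    amplitude: float = 0.1
    dip_shape: float = 0.5
    event_spacing: float | None = None
    event_jitter_sd: float = 0.25
    degron_lag: float = 3.0
    degron_slope: float = 0.5
    noise_sd: float = 0.02
    frame_interval: float = 0.2
    rise_jitter_sd: float = 0.5
    puncta_burden: float = 6.0
    clip_at_zero: bool = False
    amplitude_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.g0_end <= self.s_start < self.s_end <= self.trace_end):
            raise ValueError("require g0_end <= s_start < s_end <= trace_end")
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.dip_shape <= 0:
            raise ValueError("dip_shape must be > 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.ramp_slope < 0:
            raise ValueError("ramp_slope must be >= 0")
        if self.rise_onset < self.g0_end:
            raise ValueError("ramp onset precedes g0_end; lower ramp_offset")

    @property
    def rise_onset(self) -> float:
        """Time (h) at which the linear ramp leaves zero (CDK2 rise)."""
        if self.ramp_slope == 0:
            return self.s_start
        return self.s_start - self.ramp_offset / self.ramp_slope

    @property
    def s_duration(self) -> float:
        return self.s_end - self.s_start

    def replace(self, **kwargs) -> "StressModelConfig":
        return dataclasses.replace(self, **kwargs)


#: Regime presets.  ``cycling`` is a continuously proliferating cell: 6-h S
#: phase and a dominant fluctuation period of 2.4 h (anticorrelation lag
#: 1.2 h).  ``quiescence_release`` is mitogen-starved-then-released: 9-h S
#: phase, faster fluctuations (period 1.6 h, lag 0.8 h), twice the stress
#: burden (event count and puncta burden doubled).
_PRESETS: dict[str, StressModelConfig] = {
    "cycling": StressModelConfig(
        s_start=8.0,
        s_end=14.0,
        trace_end=17.0,
        event_spacing=2.4,
        n_events=20,
        puncta_burden=6.0,
    ),
    "quiescence_release": StressModelConfig(
        s_start=8.0,
        s_end=17.0,
        trace_end=20.0,
        event_spacing=1.6,
        event_jitter_sd=0.2,
        dip_shape=0.25,
        n_events=40,
        puncta_burden=12.0,
    ),
}

REGIMES = tuple(_PRESETS)


def preset(regime: str, **overrides) -> StressModelConfig:
    """Return the configuration preset for a regime.

    ``regime`` is ``"cycling"`` or ``"quiescence_release"`` (``"qr"`` is
    accepted as an alias).  Keyword overrides replace preset fields.
    """
    name = {"qr": "quiescence_release"}.get(regime, regime)
    try:
        cfg = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown regime {regime!r}; expected one of {REGIMES}"
        ) from None
    return cfg.replace(**overrides) if overrides else cfg


@dataclass(frozen=True)
class WashoutProtocol:
    """Drug pulse / washout protocol for exogenous replication stress.

    During ``[t_add, t_washout]`` activity is suppressed toward
    ``(1 - suppression_fraction)`` of its pre-pulse level; after washout
    the deficit decays exponentially with ``recovery_halflife`` minutes.
    """

    t_add: float = 10.0
    t_washout: float = 11.0
    suppression_fraction: float = 0.3
    recovery_halflife: float = 40.0

    def __post_init__(self) -> None:
        if not self.t_add < self.t_washout:
            raise ValueError("t_add must precede t_washout")
        if not 0.0 <= self.suppression_fraction <= 1.0:
            raise ValueError("suppression_fraction must lie in [0, 1]")
        if self.recovery_halflife <= 0:
            raise ValueError("recovery_halflife must be > 0")
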