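"""Per-cell time-series containers shared by the simulator and analysis code."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


@dataclass
class CellTrace:
    """One cell's reporter time series.

    ``ratio`` is the cytoplasmic:nuclear translocation ratio (the CDK2
    activity readout); ``nuc``/``cyto`` are the underlying intensities,
    ``degron`` the APC/C-substrate reporter intensity.  All series share
    the regular time grid ``time`` (hours).
    """

    cell_id: int
    time: np.ndarray
    ratio: np.ndarray
    nuc: np.ndarray
    cyto: np.ndarray
    degron: np.ndarray
    qc_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("ratio", "nuc", "cyto", "degron"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name!r} length differs from time")
        dt = np.diff(self.time)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("time must increase with constant spacing")

    @property
    def frame_interval(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else np.nan

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def with_ratio(self, ratio: np.ndarray) -> "CellTrace":
        return replace(self, ratio=np.asarray(ratio, dtype=float))

    def frame_at(self, t: float) -> int:
        """Index of the frame nearest to time ``t`` (h)."""
        return int(np.argmin(np.abs(self.time - t)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "frame": np.arange(self.n_frames),
                "time_h": self.time,
                "ratio": self.ratio,
                "nuc": self.nuc,
                "cyto": self.cyto,
                "degron": self.degron,
            }
        )


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    """Long-format table (cell_id, frame, time_h, ratio, nuc, cyto, degron)."""
    return pd.concat([t.to_frame() for t in traces], ignore_index=True)


def traces_from_frame(df: pd.DataFrame) -> list[CellTrace]:
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            CellTrace(
                cell_id=int(cid),
                time=grp["time_h"].to_numpy(float),
                ratio=grp["ratio"].to_numpy(float),
                nuc=grp["nuc"].to_numpy(float),
                cyto=grp["cyto"].to_numpy(float),
                degron=grp["degron"].to_numpy(float),
            )
        )
    return out
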