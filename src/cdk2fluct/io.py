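"""File I/O: trace tables, ground-truth sidecars, configs and TIFF stacks."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .config import StressModelConfig
from .synth_traces import SimulatedCell
from .traces import traces_to_frame


def save_population(cells: list[SimulatedCell], out_dir: str | Path) -> Path:
    """Write traces.csv plus a ground_truth.json sidecar for a population."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces_to_frame([c.trace for c in cells]).to_csv(out / "traces.csv", index=False)
    truth = {
        str(c.trace.cell_id): {
            "events_h": [e.t_i for e in c.true_events],
            "cdk2_rise_h": c.true_cdk2_rise,
            "apc_inactivation_h": c.true_apc_inactivation,
            "s_duration_h": c.true_s_duration,
            "recovery_halflife_min": c.true_recovery_halflife,
            "regime": c.regime,
        }
        for c in cells
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return out


def save_config(config: StressModelConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def load_config(path: str | Path) -> StressModelConfig:
    return StressModelConfig(**yaml.safe_load(Path(path).read_text()))


def save_channel_stack(
    frames: list[np.ndarray], path: str | Path, dtype=np.float32
) -> None:
    """Write one channel's frames as a frame-major multi-page TIFF."""
    tifffile.imwrite(Path(path), np.stack(frames).astype(dtype))


def load_channel_stack(path: str | Path) -> list[np.ndarray]:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return [a.astype(float) for a in arr]


def save_label_stack(labels: list[np.ndarray], path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.stack(labels).astype(np.uint16))
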