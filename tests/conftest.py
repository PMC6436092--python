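import numpy as np
import pytest

from cdk2fluct.config import StressModelConfig, preset
from cdk2fluct.image_quant import LabelMask
from cdk2fluct.synth_images import _disk_mask
from cdk2fluct.synth_traces import simulate_population
from cdk2fluct.traces import CellTrace


def disk_labels(shape, centers, radius, um_per_px=1.0):
    """Ground-truth label mask with one rasterized disk per center."""
    labels = np.zeros(shape, dtype=np.int32)
    for k, (cx, cy) in enumerate(centers, start=1):
        labels[_disk_mask(shape, cx, cy, radius)] = k
    return LabelMask(labels, um_per_px)


def brute_force_ring(mask, cell, params):
    """Per-pixel distance oracle for the perinuclear-ring definition."""
    labels = mask.labels
    own = np.argwhere(labels == cell)
    others = np.argwhere((labels != 0) & (labels != cell))
    h, w = labels.shape
    out = np.zeros((h, w), dtype=bool)
    for y in range(h):
        for x in range(w):
            if labels[y, x] != 0:
                continue
            d_own = np.sqrt(((own - (y, x)) ** 2).sum(axis=1)).min()
            if not (
                mask.to_px(params.inner_offset)
                < d_own
                <= mask.to_px(params.outer_offset)
            ):
                continue
            if len(others):
                d_oth = np.sqrt(((others - (y, x)) ** 2).sum(axis=1)).min()
                if d_oth < mask.to_px(params.neighbor_exclusion):
                    continue
            out[y, x] = True
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def cycling_population():
    """Moderate cycling-preset population shared across read-only tests."""
    return simulate_population(regime="cycling", n_cells=300, seed=1)


@pytest.fixture
def quiet_config():
    """Noise- and dip-free configuration: trace equals its ramp exactly."""
    return StressModelConfig(n_events=0, noise_sd=0.0, rise_jitter_sd=0.0)


def make_trace(time, ratio, degron=None, nuc=None, cell_id=0):
    time = np.asarray(time, float)
    ratio = np.asarray(ratio, float)
    nuc = np.ones_like(time) if nuc is None else np.asarray(nuc, float)
    degron = np.zeros_like(time) if degron is None else np.asarray(degron, float)
    return CellTrace(
        cell_id=cell_id, time=time, ratio=ratio, nuc=nuc, cyto=ratio * nuc,
        degron=degron,
    )


@pytest.fixture
def toy_trace_factory():
    return make_trace
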