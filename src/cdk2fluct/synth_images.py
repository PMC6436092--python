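"""Synthetic multi-channel microscopy renderer.

Renders nuclei, translocation-reporter partitioning and nuclear puncta
from simulated cell states, inverting the measurement model that the
quantification chain applies: the reporter channel carries the nuclear
intensity inside the nuclear disk and ``ratio x nuclear`` in a cytoplasm
annulus wider than the perinuclear measurement ring, on a spatially
constant background, with Poisson shot noise plus Gaussian read noise
applied last.  Every frame records its ground truth (label mask, true
ratios, true puncta pixel counts) so recovered measurements can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FieldSpec",
    "CellState",
    "RenderedFrame",
    "layout_grid",
    "render_frame",
    "render_puncta",
    "add_noise",
]


@dataclass(frozen=True)
class FieldSpec:
    """Imaging geometry and noise model of a rendered field."""

    height: int
    width: int
    cell_positions: tuple[tuple[float, float], ...]  # (x, y) centers, px
    um_per_px: float = 0.65
    background_level: float = 100.0
    nuclear_radius_um: float = 8.0
    cyto_outer_um: float | None = None  # default nuclear radius + 15 um
    h2b_intensity: float = 300.0
    read_noise_sd: float = 2.0
    poisson_noise: bool = True

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")
        r = self.nuclear_radius_px
        for x, y in self.cell_positions:
            if not (r <= x <= self.width - 1 - r and r <= y <= self.height - 1 - r):
                raise ValueError(f"nucleus at ({x}, {y}) extends off-frame")
        pos = np.asarray(self.cell_positions, dtype=float)
        for i in range(len(pos)):
            d = np.hypot(*(pos[i] - pos[i + 1 :]).T) if i + 1 < len(pos) else []
            if len(d) and np.min(d) < 2 * r:
                raise ValueError("nuclear disks overlap")

    @property
    def nuclear_radius_px(self) -> float:
        return self.nuclear_radius_um / self.um_per_px

    @property
    def cyto_outer_px(self) -> float:
        outer = (
            self.nuclear_radius_um + 15.0
            if self.cyto_outer_um is None
            else self.cyto_outer_um
        )
        return outer / self.um_per_px


@dataclass(frozen=True)
class CellState:
    """Reporter state of one cell at one frame."""

    ratio: float
    nuc_intensity: float = 1000.0
    degron: float = 0.0

    def __post_init__(self) -> None:
        if self.ratio < 0 or self.nuc_intensity < 0 or self.degron < 0:
            raise ValueError("intensities and ratio must be >= 0")


@dataclass
class RenderedFrame:
    """Rendered channels plus the ground truth that generated them."""

    channels: dict[str, np.ndarray]
    labels: np.ndarray  # ground-truth nuclear label mask (0 = background)
    frame_index: int = 0
    true_ratio: dict[int, float] = field(default_factory=dict)
    true_puncta_px: dict[int, int] = field(default_factory=dict)
    spec: FieldSpec | None = None


def layout_grid(
    n_cells: int,
    nuclear_radius_um: float = 8.0,
    um_per_px: float = 0.65,
    pitch_um: float = 50.0,
    **spec_kwargs,
) -> FieldSpec:
    """FieldSpec with ``n_cells`` nuclei on a square grid of given pitch."""
    pitch = pitch_um / um_per_px
    cols = int(np.ceil(np.sqrt(n_cells)))
    rows = int(np.ceil(n_cells / cols))
    positions = tuple(
        (pitch / 2 + (i % cols) * pitch, pitch / 2 + (i // cols) * pitch)
        for i in range(n_cells)
    )
    return FieldSpec(
        height=int(np.ceil(rows * pitch)),
        width=int(np.ceil(cols * pitch)),
        cell_positions=positions,
        um_per_px=um_per_px,
        nuclear_radius_um=nuclear_radius_um,
        **spec_kwargs,
    )


def _disk_mask(shape, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


CHANNELS = ("h2b", "dhb", "degron", "h2ax")


def render_frame(
    cells: list[CellState],
    spec: FieldSpec,
    stream: np.random.Generator | None = None,
    frame_index: int = 0,
    apply_noise: bool = True,
) -> RenderedFrame:
    """Render one multi-channel frame from per-cell reporter states.

    Channels: ``h2b`` nuclear marker disks, ``dhb`` translocation
    reporter (nuclear intensity in the disk, ratio-scaled intensity in
    the cytoplasm annulus), ``degron`` nuclear degron reporter, ``h2ax``
    empty (populated by :func:`render_puncta`).  Cell ``k`` (1-based
    label) uses ``spec.cell_positions[k-1]``.
    """
    if len(cells) > len(spec.cell_positions):
        raise ValueError("more cell states than positions in the field spec")
    shape = (spec.height, spec.width)
    chans = {name: np.zeros(shape, dtype=float) for name in CHANNELS}
    labels = np.zeros(shape, dtype=np.int32)
    truth: dict[int, float] = {}
    r_nuc, r_out = spec.nuclear_radius_px, spec.cyto_outer_px
    for k, cell in enumerate(cells, start=1):
        x, y = spec.cell_positions[k - 1]
        nuc = _disk_mask(shape, x, y, r_nuc)
        cyto = _disk_mask(shape, x, y, r_out) & ~nuc
        labels[nuc] = k
        chans["h2b"][nuc] += spec.h2b_intensity
        chans["dhb"][nuc] += cell.nuc_intensity
        chans["dhb"][cyto] += cell.ratio * cell.nuc_intensity
        chans["degron"][nuc] += cell.degron
        truth[k] = cell.ratio
    for img in chans.values():
        img += spec.background_level
    frame = RenderedFrame(
        channels=chans,
        labels=labels,
        frame_index=frame_index,
        true_ratio=truth,
        true_puncta_px={k: 0 for k in truth},
        spec=spec,
    )
    if apply_noise:
        if stream is None:
            raise ValueError("apply_noise=True requires a random stream")
        frame = add_noise(frame, spec, stream)
    return frame


def add_noise(
    frame: RenderedFrame, spec: FieldSpec, stream: np.random.Generator
) -> RenderedFrame:
    """Apply Poisson shot noise and Gaussian read noise to every channel."""
    noisy = {}
    for name, img in frame.channels.items():
        out = (
            stream.poisson(np.maximum(img, 0)).astype(float)
            if spec.poisson_noise
            else img.astype(float)
        )
        if spec.read_noise_sd > 0:
            out = out + stream.normal(0.0, spec.read_noise_sd, img.shape)
        noisy[name] = out
    return RenderedFrame(
        channels=noisy,
        labels=frame.labels,
        frame_index=frame.frame_index,
        true_ratio=dict(frame.true_ratio),
        true_puncta_px=dict(frame.true_puncta_px),
        spec=spec,
    )


def render_puncta(
    frame: RenderedFrame,
    cell: int,
    n_puncta: int,
    punctum_radius_um: float,
    punctum_intensity: float,
    stream: np.random.Generator,
    max_tries: int = 500,
) -> RenderedFrame:
    """Add non-overlapping bright puncta inside one cell's nucleus.

    Puncta are disks added to the ``h2ax`` channel; centers are kept far
    enough apart that the rasterized disks are disjoint, so the cell's
    ground-truth puncta pixel count (the rasterized union area) equals
    the sum of the individual disk areas.  Intended to run on a
    noise-free frame, before :func:`add_noise`.
    """
    if frame.spec is None:
        raise ValueError("frame carries no field spec")
    if n_puncta == 0:
        return frame
    spec = frame.spec
    r_px = punctum_radius_um / spec.um_per_px
    nucleus = frame.labels == cell
    if not nucleus.any():
        raise ValueError(f"cell {cell} not present in the frame")
    ys, xs = np.nonzero(nucleus)
    h2ax = frame.channels["h2ax"]
    union = np.zeros_like(nucleus)
    centers: list[tuple[float, float]] = []
    placed = 0
    for _ in range(max_tries):
        if placed == n_puncta:
            break
        j = stream.integers(0, len(xs))
        cx, cy = float(xs[j]), float(ys[j])
        # keep the punctum inside the nucleus and clear of earlier ones
        x0, y0 = np.mean(xs), np.mean(ys)
        if np.hypot(cx - x0, cy - y0) > spec.nuclear_radius_px - r_px:
            continue
        if any(np.hypot(cx - px, cy - py) < 2 * r_px + 1 for px, py in centers):
            continue
        disk = _disk_mask(nucleus.shape, cx, cy, r_px)
        h2ax[disk] += punctum_intensity
        union |= disk
        centers.append((cx, cy))
        placed += 1
    if placed < n_puncta:
        raise RuntimeError(
            f"placed only {placed}/{n_puncta} puncta after {max_tries} tries"
        )
    frame.true_puncta_px[cell] = int(union.sum())
    return frame
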