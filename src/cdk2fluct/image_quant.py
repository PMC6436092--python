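"""Fixed- and live-cell image quantification chain.

Nuclear segmentation, global background estimation, perinuclear-ring
cytoplasmic measurement, translocation-ratio computation, puncta pixel
counting via top-hat filtering, and frame-to-frame tracking.  The
reporter readout per cell is ``cyto_p75 / nuc_median``: the 75th
percentile of the above-background perinuclear ring over the median
nuclear intensity, both after global background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, white_tophat
from skimage.segmentation import watershed

__all__ = [
    "LabelMask",
    "RingParams",
    "CellMeasurement",
    "segment_nuclei",
    "estimate_background",
    "ring_mask",
    "measure_cell",
    "measure_frame",
    "quantify_h2ax",
    "quantify_h2ax_frame",
    "track_cells",
    "quantify_movie",
]


@dataclass
class LabelMask:
    """Integer nuclear label image (0 = background) with its pixel size."""

    labels: np.ndarray
    um_per_px: float = 0.65

    def __post_init__(self) -> None:
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")

    @property
    def cell_ids(self) -> list[int]:
        return [int(k) for k in np.unique(self.labels) if k != 0]

    def to_um(self, px: float) -> float:
        return px * self.um_per_px

    def to_px(self, um: float) -> float:
        return um / self.um_per_px


@dataclass(frozen=True)
class RingParams:
    """Perinuclear measurement ring: 2-10 um outside the nuclear mask,
    excluding anything within 10 um of another nucleus."""

    inner_offset: float = 2.0
    outer_offset: float = 10.0
    neighbor_exclusion: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_offset < self.outer_offset:
            raise ValueError("require 0 < inner_offset < outer_offset")


@dataclass
class CellMeasurement:
    """Image-derived quantities for one cell at one frame."""

    cell_id: int
    frame: int = 0
    nuc_median: float = np.nan
    cyto_p75: float = np.nan
    ratio: float | None = None
    h2ax_pixels: int = 0
    stain_values: dict[str, float] = field(default_factory=dict)


def segment_nuclei(
    nuclear_channel: np.ndarray,
    min_area: int = 80,
    max_area: int = 10_000,
    um_per_px: float = 0.65,
    smooth_sigma: float = 1.0,
) -> LabelMask:
    """Segment nuclei from a nuclear-marker channel.

    Otsu threshold on the log-transformed (smoothed) image, hole filling,
    distance-transform watershed declumping, and area gating.  A blank or
    degenerate image yields an empty mask rather than an error.
    """
    img = np.asarray(nuclear_channel, dtype=float)
    sm = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    logim = np.log1p(np.maximum(sm - sm.min(), 0.0))
    if np.ptp(logim) == 0:
        return LabelMask(np.zeros(img.shape, dtype=np.int32), um_per_px)
    binary = logim > threshold_otsu(logim)
    binary = ndi.binary_fill_holes(binary)
    if not binary.any():
        return LabelMask(np.zeros(img.shape, dtype=np.int32), um_per_px)

    distance = ndi.distance_transform_edt(binary)
    min_dist = max(3, int(round(np.sqrt(min_area / np.pi))))
    coords = peak_local_max(
        gaussian(distance, sigma=1.0),
        min_distance=min_dist,
        labels=cc_label(binary),
        num_peaks_per_label=8,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-distance, markers, mask=binary)

    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for k in np.unique(labels):
        if k == 0:
            continue
        region = labels == k
        if min_area <= region.sum() <= max_area:
            out[region] = next_id
            next_id += 1
    return LabelMask(out, um_per_px)


def estimate_background(
    image: np.ndarray, mask: LabelMask, dilation: float = 50.0
) -> float:
    """Global background: median intensity outside all dilated nuclear masks.

    Masks are dilated by ``dilation`` micrometres (distance-transform
    equivalent of a disk dilation).
    """
    dist = ndi.distance_transform_edt(mask.labels == 0)
    bg = dist > mask.to_px(dilation)
    if not bg.any():
        raise ValueError(
            "no background pixels remain after dilation; use a larger field "
            "or a smaller dilation"
        )
    return float(np.median(np.asarray(image, dtype=float)[bg]))


def ring_mask(mask: LabelMask, cell: int, params: RingParams) -> np.ndarray:
    """Perinuclear ring of one cell, with neighbor exclusion.

    Pixels whose distance to the cell's nuclear mask lies in
    ``(inner_offset, outer_offset]`` um, outside every nuclear mask and
    not within ``neighbor_exclusion`` um of any other nucleus.
    """
    own = mask.labels == cell
    if not own.any():
        raise ValueError(f"cell {cell} not present in mask")
    d_own = ndi.distance_transform_edt(~own)
    ring = (
        (d_own > mask.to_px(params.inner_offset))
        & (d_own <= mask.to_px(params.outer_offset))
        & (mask.labels == 0)
    )
    others = (mask.labels != 0) & ~own
    if others.any():
        d_other = ndi.distance_transform_edt(~others)
        ring &= d_other >= mask.to_px(params.neighbor_exclusion)
    return ring


def measure_cell(
    channels: dict[str, np.ndarray],
    mask: LabelMask,
    cell: int,
    params: RingParams = RingParams(),
    backgrounds: dict[str, float] | None = None,
    reporter_channel: str = "dhb",
    frame: int = 0,
) -> CellMeasurement:
    """Measure one cell: reporter ratio plus nuclear stain intensities.

    Per-channel global background is subtracted first.  The reporter
    ratio is the 75th percentile (linear interpolation between order
    statistics) of strictly-positive ring pixels over the median nuclear
    intensity; it is left undefined (None) when no ring pixel remains
    above background.  Channels other than the nuclear marker and the
    reporter are measured as background-subtracted nuclear medians.
    """
    if backgrounds is None:
        backgrounds = {
            name: estimate_background(img, mask) for name, img in channels.items()
        }
    nucleus = mask.labels == cell
    if not nucleus.any():
        raise ValueError(f"cell {cell} not present in mask")
    meas = CellMeasurement(cell_id=cell, frame=frame)

    rep = np.asarray(channels[reporter_channel], float) - backgrounds[reporter_channel]
    meas.nuc_median = float(np.median(rep[nucleus]))
    ring = ring_mask(mask, cell, params)
    ring_vals = rep[ring]
    ring_vals = ring_vals[ring_vals > 0]  # only above-background pixels
    if len(ring_vals):
        meas.cyto_p75 = float(np.percentile(ring_vals, 75))
        if meas.nuc_median != 0:
            meas.ratio = meas.cyto_p75 / meas.nuc_median
    for name, img in channels.items():
        if name in (reporter_channel, "h2b"):
            continue
        vals = np.asarray(img, float)[nucleus] - backgrounds[name]
        meas.stain_values[name] = float(np.median(vals))
    return meas


def measure_frame(
    channels: dict[str, np.ndarray],
    mask: LabelMask,
    params: RingParams = RingParams(),
    frame: int = 0,
    reporter_channel: str = "dhb",
    background_dilation: float = 50.0,
) -> list[CellMeasurement]:
    """Measure every cell in a frame with shared background estimates."""
    backgrounds = {
        name: estimate_background(img, mask, background_dilation)
        for name, img in channels.items()
    }
    return [
        measure_cell(
            channels,
            mask,
            cid,
            params,
            backgrounds,
            reporter_channel=reporter_channel,
            frame=frame,
        )
        for cid in mask.cell_ids
    ]


def quantify_h2ax_frame(
    h2ax_channel: np.ndarray,
    mask: LabelMask,
    kernel_radius: float = 4.0,
    abs_threshold: float | None = None,
) -> dict[int, int]:
    """Puncta pixel counts for every cell of a frame (top-hat computed once)."""
    img = np.asarray(h2ax_channel, dtype=float)
    radius_px = max(1, int(round(mask.to_px(kernel_radius))))
    filtered = white_tophat(img, footprint=disk(radius_px))
    if abs_threshold is None:
        med = np.median(filtered)
        sigma = 1.4826 * np.median(np.abs(filtered - med))
        abs_threshold = med + 5.0 * sigma
    fg = filtered > abs_threshold
    return {
        cid: int(np.count_nonzero(fg[mask.labels == cid])) for cid in mask.cell_ids
    }


def quantify_h2ax(
    h2ax_channel: np.ndarray,
    mask: LabelMask,
    cell: int,
    kernel_radius: float = 4.0,
    abs_threshold: float | None = None,
) -> int:
    """Puncta burden: above-threshold pixel count after top-hat filtering.

    A white top-hat with a circular structuring element of
    ``kernel_radius`` um keeps only bright structures smaller than the
    kernel; pixels whose filtered value exceeds ``abs_threshold`` are
    counted inside the cell's nuclear mask.  The default threshold is
    the filtered image's median plus five robust (MAD-based) standard
    deviations.
    """
    if not np.any(mask.labels == cell):
        raise ValueError(f"cell {cell} not present in mask")
    return quantify_h2ax_frame(h2ax_channel, mask, kernel_radius, abs_threshold)[cell]


def _centroids(mask: LabelMask) -> dict[int, tuple[float, float]]:
    out = {}
    for k in mask.cell_ids:
        ys, xs = np.nonzero(mask.labels == k)
        out[k] = (float(np.mean(ys)), float(np.mean(xs)))
    return out


def track_cells(
    masks: list[LabelMask], max_displacement: float = 20.0
) -> pd.DataFrame:
    """Greedy mutual-nearest-centroid linking across frames.

    Labels in consecutive frames are linked when each is the other's
    nearest centroid and the displacement is below ``max_displacement``
    um per frame; unmatched labels start new tracks.  Returns a table
    with columns (frame, label, cell_id, y, x).
    """
    rows = []
    next_track = 1
    prev: dict[int, int] = {}  # label in previous frame -> track id
    prev_cent: dict[int, tuple[float, float]] = {}
    for f, mask in enumerate(masks):
        cents = _centroids(mask)
        gate = mask.to_px(max_displacement)
        assign: dict[int, int] = {}
        if prev:
            for lab, (cy, cx) in cents.items():
                dists = {
                    pl: np.hypot(cy - py, cx - px)
                    for pl, (py, px) in prev_cent.items()
                }
                if not dists:
                    continue
                best = min(dists, key=dists.get)
                if dists[best] > gate:
                    continue
                # mutual check: is this label also the nearest to `best`?
                back = {
                    l2: np.hypot(
                        cents[l2][0] - prev_cent[best][0],
                        cents[l2][1] - prev_cent[best][1],
                    )
                    for l2 in cents
                }
                if min(back, key=back.get) == lab and best in prev:
                    assign[lab] = prev[best]
        used = set()
        new_prev: dict[int, int] = {}
        for lab, (cy, cx) in cents.items():
            tid = assign.get(lab)
            if tid is None or tid in used:
                tid = next_track
                next_track += 1
            used.add(tid)
            new_prev[lab] = tid
            rows.append({"frame": f, "label": lab, "cell_id": tid, "y": cy, "x": cx})
        prev, prev_cent = new_prev, cents
    return pd.DataFrame(rows, columns=["frame", "label", "cell_id", "y", "x"])


def quantify_movie(
    channel_stacks: dict[str, list[np.ndarray]],
    um_per_px: float = 0.65,
    params: RingParams = RingParams(),
    min_area: int = 80,
    max_area: int = 10_000,
    frame_interval: float = 0.2,
    nuclear_channel: str = "h2b",
    background_dilation: float = 50.0,
) -> pd.DataFrame:
    """Full pixels-to-traces chain for a multi-channel time-lapse stack.

    Segments the nuclear channel per frame, measures every cell, tracks
    nuclei across frames and returns a long-format trace table
    (cell_id, frame, time_h, ratio, nuc, cyto, degron).
    """
    n_frames = len(channel_stacks[nuclear_channel])
    masks, all_meas = [], []
    for f in range(n_frames):
        mask = segment_nuclei(
            channel_stacks[nuclear_channel][f], min_area, max_area, um_per_px
        )
        masks.append(mask)
        chans = {name: stack[f] for name, stack in channel_stacks.items()}
        all_meas.append(
            {
                m.cell_id: m
                for m in measure_frame(
                    chans, mask, params, f, background_dilation=background_dilation
                )
            }
        )
    tracks = track_cells(masks)
    rows = []
    for _, r in tracks.iterrows():
        m = all_meas[int(r.frame)].get(int(r.label))
        if m is None:
            continue
        rows.append(
            {
                "cell_id": int(r.cell_id),
                "frame": int(r.frame),
                "time_h": r.frame * frame_interval,
                "ratio": np.nan if m.ratio is None else m.ratio,
                "nuc": m.nuc_median,
                "cyto": m.cyto_p75,
                "degron": m.stain_values.get("degron", np.nan),
            }
        )
    return pd.DataFrame(rows).sort_values(["cell_id", "frame"]).reset_index(drop=True)
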