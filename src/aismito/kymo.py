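"""Kymographs along the axon and trafficking-event detection.

Each kymograph row is the maximum intensity across a perpendicular swath at
one arclength, per frame. Events are extracted by removing stationary
structure (per-row temporal median), thresholding, connecting ridge pixels
and fitting each component's distance-vs-time track. Only tracks that pass
the displacement/speed gates and whose distance range overlaps the cluster
span ("went past the cluster") are counted; the stationary cluster band is
never an event. An event is cluster-origin iff it is red and its track
starts inside the cluster span.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from ._geometry import perpendicular_offsets, resample_path, sample_image, swath_coordinates
from .errors import ValidationError
from .io import ImageStack, PathAnnotation


@dataclass
class Kymograph:
    """Distance-time matrices, one per channel, on shared axes."""

    data: dict[str, np.ndarray]  # channel -> (n_positions, n_frames)
    step_um: float
    interval_s: float
    cluster_span_um: tuple[float, float] | None = None

    def __post_init__(self):
        if not self.step_um > 0 or not self.interval_s > 0:
            raise ValidationError("step_um and interval_s must be positive")
        shapes = {v.shape for v in self.data.values()}
        if len(shapes) != 1:
            raise ValidationError("all channels must share the kymograph axes")

    @property
    def n_positions(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def n_frames(self) -> int:
        return next(iter(self.data.values())).shape[1]


@dataclass
class TrafficEvent:
    t_start_s: float
    t_end_s: float
    x_start_um: float
    x_end_um: float
    direction: str  # anterograde | retrograde
    origin: str  # cluster | other
    channel: str
    mean_speed_um_s: float


def build_kymograph(
    stack: ImageStack,
    path: PathAnnotation,
    width_um: float = 1.5,
    step_um: float | None = None,
    cluster_span_um: tuple[float, float] | None = None,
) -> Kymograph:
    """Kymograph of every channel of a time-lapse along ``path`` (distance
    axis from the somatic end)."""
    if not stack.has_time:
        raise ValidationError("build_kymograph needs a multi-frame stack")
    if stack.n_frames < 2:
        raise ValidationError("a kymograph needs at least two frames")
    step_um = step_um or stack.pixel_size_um
    pts, normals, arcs = resample_path(path.points_px, stack.pixel_size_um, step_um)
    offs = perpendicular_offsets(width_um, stack.pixel_size_um)
    coords = swath_coordinates(pts, normals, offs, stack.pixel_size_um)
    data = {}
    for name in stack.channel_names:
        movie = stack.channel(name)
        rows = np.empty((len(arcs), stack.n_frames))
        for t in range(stack.n_frames):
            rows[:, t] = sample_image(movie[t], coords).max(axis=1)
        data[name] = rows
    return Kymograph(data, step_um, stack.frame_interval_s, cluster_span_um)


def _component_track(component_mask: np.ndarray, block: np.ndarray):
    """Intensity-weighted centroid row per occupied time column."""
    cols = np.where(component_mask.any(axis=0))[0]
    xs = []
    for c in cols:
        w = np.where(component_mask[:, c], block[:, c], 0.0)
        rows = np.arange(component_mask.shape[0])
        xs.append(float((rows * w).sum() / w.sum()))
    return cols, np.asarray(xs)


def detect_and_classify_events(
    kymo: Kymograph,
    cluster_span_um: tuple[float, float] | None = None,
    min_displacement_um: float = 2.0,
    min_speed_um_s: float = 0.1,
    origin_tolerance_um: float = 1.0,
    require_full_crossing: bool = False,
) -> list[TrafficEvent]:
    """Detect moving particles in a two-channel kymograph and classify them.

    ``require_full_crossing`` switches the "went past the cluster" gate from
    range overlap (default, literal reading) to full traversal of the span.
    Without a red channel all events are labelled origin=other.
    """
    span = cluster_span_um or kymo.cluster_span_um
    if span is None:
        raise ValidationError("cluster_span_um required (none stored on the kymograph)")
    has_red = "red" in kymo.data
    events: list[TrafficEvent] = []
    for channel, km in kymo.data.items():
        resid = km - np.median(km, axis=1, keepdims=True)
        resid = np.clip(resid, 0, None)
        if resid.max() <= 0:
            continue
        thr = threshold_otsu(resid)
        mask = resid > thr
        labels = label(mask, connectivity=2)
        for prop in regionprops(labels):
            comp = labels == prop.label
            cols, xs_rows = _component_track(comp, resid)
            if cols.size < 3:
                continue
            ts = cols * kymo.interval_s
            xs = xs_rows * kymo.step_um
            displacement = xs[-1] - xs[0]
            if abs(displacement) < min_displacement_um:
                continue
            speed = float(np.polyfit(ts, xs, 1)[0])
            if abs(speed) < min_speed_um_s:
                continue
            x_lo, x_hi = float(xs.min()), float(xs.max())
            if require_full_crossing:
                passes = x_lo <= span[0] and x_hi >= span[1]
            else:
                passes = x_hi >= span[0] and x_lo <= span[1]
            if not passes:
                continue
            origin = (
                "cluster"
                if has_red
                and channel == "red"
                and span[0] - origin_tolerance_um <= xs[0] <= span[1] + origin_tolerance_um
                else "other"
            )
            events.append(
                TrafficEvent(
                    t_start_s=float(ts[0]),
                    t_end_s=float(ts[-1]),
                    x_start_um=float(xs[0]),
                    x_end_um=float(xs[-1]),
                    direction="anterograde" if displacement > 0 else "retrograde",
                    origin=origin,
                    channel=channel,
                    mean_speed_um_s=speed,
                )
            )
    if not has_red and events:
        import warnings

        warnings.warn("no red channel: all events labelled origin=other", stacklevel=2)
    events.sort(key=lambda e: (e.t_start_s, e.x_start_um))
    return events


def event_fractions(events_per_cell: dict[str, list[TrafficEvent]]) -> tuple[pd.DataFrame, dict]:
    """Per-cell event fractions and cohort means.

    Each cell's events are expressed as fractions of that cell's total
    (cluster vs other; anterograde vs retrograde). Cells without any event are
    excluded; the cohort mean is the unweighted mean of per-cell fractions.
    """
    rows = []
    for cell, events in events_per_cell.items():
        n = len(events)
        if n == 0:
            continue  # cells with no mitochondrial movement are excluded
        n_cluster = sum(e.origin == "cluster" for e in events)
        n_antero = sum(e.direction == "anterograde" for e in events)
        rows.append(
            {
                "cell_id": cell,
                "n_events": n,
                "fraction_cluster": n_cluster / n,
                "fraction_other": (n - n_cluster) / n,
                "fraction_anterograde": n_antero / n,
                "fraction_retrograde": (n - n_antero) / n,
            }
        )
    if not rows:
        raise ValidationError("all cells excluded (no trafficking events)")
    df = pd.DataFrame(rows)
    cohort = {
        c: float(df[c].mean())
        for c in ["fraction_cluster", "fraction_other", "fraction_anterograde", "fraction_retrograde"]
    }
    cohort["n_cells"] = int(len(df))
    return df, cohort
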