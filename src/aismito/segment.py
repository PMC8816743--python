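"""Mitochondria segmentation, somatodendritic ROIs and normalized intensities.

Somatic TAU is quantified semi-automatically: somatodendritic regions come
from the MAP2 channel, the mean background fluorescence of each image is
subtracted, and treated cells are normalized to the mean of control cells
(so the control group mean is exactly 1). Pixel-classifier segmentation of
mitochondria is replaced by deterministic, configurable thresholding that
produces the same downstream object — a binary mask.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_local, threshold_otsu, threshold_triangle
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk, remove_small_objects

from .errors import NoSomaError, ValidationError
from .io import CellAnnotations, ImageStack, RoiAnnotation


@dataclass
class SegmentationConfig:
    method: str = "global_otsu"  # global_otsu | adaptive_local | fixed
    fixed_threshold: float | None = None
    local_window_um: float = 5.0
    min_object_area_um2: float = 0.15

    def __post_init__(self):
        if self.method not in ("global_otsu", "adaptive_local", "fixed"):
            raise ValidationError(f"unknown segmentation method {self.method!r}")
        if self.method == "fixed" and self.fixed_threshold is None:
            raise ValidationError("fixed_threshold required when method='fixed'")
        if self.method != "fixed" and self.fixed_threshold is not None:
            raise ValidationError("fixed_threshold only valid with method='fixed'")
        if not self.local_window_um > 0:
            raise ValidationError("local_window_um must be positive")


@dataclass
class SomaticMeasurement:
    cell_id: str
    condition: str
    raw_mean: float
    background: float
    corrected: float
    normalized: float | None = None


def segment_mitochondria(
    stack: ImageStack, channel: str = "MITO", config: SegmentationConfig | None = None
) -> np.ndarray:
    """Binary foreground mask of the mitochondrial channel.

    The default global Otsu threshold adapts to each cell's overall intensity
    (accounting for expression-level differences between cells); objects
    smaller than ``min_object_area_um2`` are removed. An empty image yields an
    empty mask.
    """
    config = config or SegmentationConfig()
    img = np.asarray(stack.channel(channel), dtype=float)
    if img.ndim != 2:
        raise ValidationError("segment_mitochondria expects a single-frame stack")
    if img.max() == img.min():
        return np.zeros_like(img, dtype=bool)
    if config.method == "global_otsu":
        mask = img > threshold_otsu(img)
    elif config.method == "fixed":
        mask = img > config.fixed_threshold
    else:
        block = int(config.local_window_um / stack.pixel_size_um) | 1  # odd
        mask = img > threshold_local(img, block_size=max(3, block), offset=0)
    min_px = int(np.ceil(config.min_object_area_um2 / stack.pixel_size_um**2))
    if min_px > 1:
        mask = remove_small_objects(mask, max_size=min_px - 1)
    return mask


@dataclass
class SomaRegion:
    cell_id: str
    soma_mask: np.ndarray
    dendrite_mask: np.ndarray
    centroid_px: tuple[float, float]  # (x, y)


def somatodendritic_rois(
    stack: ImageStack,
    channel: str = "MAP2",
    min_soma_area_um2: float = 80.0,
    max_eccentricity: float = 0.9,
    core_radius_um: float = 3.0,
) -> list[SomaRegion]:
    """Soma and dendrite masks from the MAP2 channel.

    The MAP2 mask is thresholded (Otsu); soma candidates are the thick parts
    of the mask (distance-to-background >= ``core_radius_um``), grown back by
    the same radius. Candidates must pass the area and eccentricity gates.
    Remaining MAP2-positive pixels form the dendritic mask.
    """
    img = np.asarray(stack.channel(channel), dtype=float)
    if img.max() == img.min():
        raise NoSomaError("blank MAP2 channel")
    # triangle threshold: robust for dominant-background fluorescence, keeps
    # the dimmer dendrites that Otsu tends to cut away next to a bright soma
    mask = img > threshold_triangle(img)
    mask = ndimage.binary_fill_holes(mask)
    dist_um = ndimage.distance_transform_edt(mask) * stack.pixel_size_um
    cores = dist_um >= core_radius_um
    core_labels = label(cores)
    regions = []
    grow = disk(int(round(core_radius_um / stack.pixel_size_um)))
    for i, prop in enumerate(regionprops(core_labels)):
        soma = dilation(core_labels == prop.label, grow) & mask
        sprop = regionprops(soma.astype(int))[0]
        area_um2 = sprop.area * stack.pixel_size_um**2
        if area_um2 < min_soma_area_um2 or sprop.eccentricity > max_eccentricity:
            continue
        cy, cx = sprop.centroid
        regions.append(SomaRegion(f"cell{i}", soma, np.zeros_like(soma), (cx, cy)))
    if not regions:
        raise NoSomaError("no MAP2 component passed the soma gates")
    all_soma = np.any([r.soma_mask for r in regions], axis=0)
    dend = mask & ~all_soma
    for r in regions:
        r.dendrite_mask = dend
    return regions


def estimate_background(
    stack: ImageStack,
    channel: str,
    background_roi: RoiAnnotation | None = None,
    cell_mask: np.ndarray | None = None,
) -> float:
    """Mean background fluorescence of one image: the mean inside an annotated
    background ROI when available, otherwise the mean of the lowest decile of
    pixels outside all cell masks."""
    img = np.asarray(stack.channel(channel), dtype=float)
    if img.ndim != 2:
        raise ValidationError("estimate_background expects a single-frame stack")
    if background_roi is not None:
        m = roi_mask(background_roi, img.shape)
        return float(img[m].mean())
    if cell_mask is None:
        cell_mask = np.zeros(img.shape, dtype=bool)
    outside = img[~cell_mask]
    if outside.size == 0:
        raise ValidationError("no non-cell pixels available for background estimation")
    k = max(1, outside.size // 10)
    return float(np.sort(outside, kind="stable")[:k].mean())


def roi_mask(roi: RoiAnnotation, shape_yx: tuple[int, int]) -> np.ndarray:
    rr, cc = draw_polygon(roi.polygon_px[:, 1], roi.polygon_px[:, 0], shape=shape_yx)
    m = np.zeros(shape_yx, dtype=bool)
    m[rr, cc] = True
    return m


def _default_cell_mask(stack: ImageStack, channel: str = "MAP2") -> np.ndarray:
    img = np.asarray(stack.channel(channel), dtype=float)
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    mask = img > threshold_triangle(img)
    return dilation(mask, disk(3))


def measure_somatic_intensity(
    stack: ImageStack,
    channel: str = "TAU",
    cell_id: str = "cell0",
    condition: str = "",
    soma_mask: np.ndarray | None = None,
    annotations: CellAnnotations | None = None,
) -> SomaticMeasurement:
    """Background-corrected mean somatic intensity of one cell in one image."""
    if soma_mask is None:
        if annotations is not None:
            try:
                soma_mask = roi_mask(annotations.roi(cell_id, "soma"), stack.shape_yx)
            except ValidationError:
                soma_mask = None
        if soma_mask is None:
            soma_mask = somatodendritic_rois(stack)[0].soma_mask
    bg_roi = None
    if annotations is not None:
        try:
            bg_roi = annotations.roi(cell_id, "background")
        except ValidationError:
            bg_roi = None
    background = estimate_background(
        stack, channel, background_roi=bg_roi, cell_mask=_default_cell_mask(stack)
    )
    raw = float(np.asarray(stack.channel(channel), dtype=float)[soma_mask].mean())
    return SomaticMeasurement(cell_id, condition, raw, background, raw - background)


def normalize_to_control(
    measurements: list[SomaticMeasurement], control_condition: str
) -> pd.DataFrame:
    """Fold-change table: corrected somatic intensity divided by the mean
    corrected intensity of control cells (control mean = 1 by construction)."""
    ctrl = [m.corrected for m in measurements if m.condition == control_condition]
    if not ctrl:
        raise ValidationError(f"no cells with control condition {control_condition!r}")
    ctrl_mean = float(np.mean(ctrl))
    if ctrl_mean <= 0:
        raise ValidationError("control corrected mean is <= 0; cannot normalize")
    rows = []
    for m in measurements:
        m.normalized = m.corrected / ctrl_mean
        rows.append(
            {
                "cell_id": m.cell_id,
                "condition": m.condition,
                "raw_mean": m.raw_mean,
                "background": m.background,
                "corrected": m.corrected,
                "normalized": m.normalized,
            }
        )
    return pd.DataFrame(rows)


def somatic_intensity_foldchange(
    stacks_by_condition: dict[str, list],
    control_condition: str,
    channel: str = "TAU",
    annotations_by_condition: dict[str, list] | None = None,
) -> pd.DataFrame:
    """Fold-change quantification over a whole experiment.

    ``stacks_by_condition`` maps condition name to a list of single-cell
    stacks; optional ``annotations_by_condition`` provides matching
    :class:`CellAnnotations` (used for soma/background ROIs when present).
    """
    if control_condition not in stacks_by_condition:
        raise ValidationError(f"control condition {control_condition!r} absent")
    measurements = []
    for cond, stacks in stacks_by_condition.items():
        anns = (annotations_by_condition or {}).get(cond, [None] * len(stacks))
        for i, (stack, ann) in enumerate(zip(stacks, anns)):
            inner_id = ann.cell_ids[0] if ann is not None and ann.cell_ids else "cell0"
            m = measure_somatic_intensity(
                stack, channel=channel, cell_id=inner_id, condition=cond, annotations=ann
            )
            m.cell_id = f"{cond}_{i}_{inner_id}"  # unique across the experiment
            measurements.append(m)
    return normalize_to_control(measurements, control_condition)


def map2_polarity_index(
    stack: ImageStack,
    soma_mask: np.ndarray,
    dendrite_mask: np.ndarray,
    channel: str = "MAP2",
    background: float | None = None,
) -> float:
    """Somatic mean divided by the dendritic level, both background-corrected.

    The dendritic level is the median intensity over the dendritic mask: the
    automatically derived mask unavoidably contains a few axonal/edge pixels,
    and the median is robust to them where the mean is not.
    """
    if not dendrite_mask.any():
        raise ValidationError("dendritic mask is empty")
    img = np.asarray(stack.channel(channel), dtype=float)
    if background is None:
        background = estimate_background(stack, channel, cell_mask=_default_cell_mask(stack))
    dend = np.median(img[dendrite_mask]) - background
    if dend <= 0:
        raise ValidationError("dendritic corrected mean <= 0")
    return float((img[soma_mask].mean() - background) / dend)


def roi_timeseries(
    stack: ImageStack,
    rois: list[RoiAnnotation],
    channel: str,
    background_roi: RoiAnnotation | None = None,
) -> pd.DataFrame:
    """Per-ROI background-corrected intensity trace, normalized to frame 0.

    Background defaults to the lowest decile of pixels outside all listed ROIs,
    recomputed per frame.
    """
    if not stack.has_time:
        raise ValidationError("roi_timeseries needs a time axis")
    movie = np.asarray(stack.channel(channel), dtype=float)
    shape = movie.shape[1:]
    masks = {}
    for r in rois:
        m = roi_mask(r, shape)
        if not m.any():
            raise ValidationError(f"ROI {r.cell_id!r} lies outside the image")
        masks[r.cell_id] = m
    union = np.any(list(masks.values()), axis=0)
    bg_mask = roi_mask(background_roi, shape) if background_roi is not None else None
    rows = {"time_s": np.arange(movie.shape[0]) * stack.frame_interval_s}
    traces = {}
    for t in range(movie.shape[0]):
        frame = movie[t]
        if bg_mask is not None:
            bg = frame[bg_mask].mean()
        else:
            outside = frame[~union]
            k = max(1, outside.size // 10)
            bg = np.sort(outside, kind="stable")[:k].mean()
        for name, m in masks.items():
            traces.setdefault(name, []).append(frame[m].mean() - bg)
    for name, vals in traces.items():
        vals = np.asarray(vals)
        if vals[0] == 0:
            raise ValidationError(f"ROI {name!r} has zero corrected intensity at frame 0")
        rows[name] = vals / vals[0]
    return pd.DataFrame(rows)
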