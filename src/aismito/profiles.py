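"""Arclength intensity profiles, AIS-start detection, aligned presence profiles.

The AIS start is located on the AIS-marker (ANKYRIN-G/TRIM46-like) line
profile: the profile is smoothed with a 1 µm centred sliding mean and the
start is the smallest arclength at which the smoothed profile first reaches
30% of its maximum. Binary presence profiles from segmented mitochondria are
aligned to that start and averaged with a biological-replicate-weighted mean
(per-replicate cell means first, then the unweighted mean across replicates).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import (
    check_inside,
    perpendicular_offsets,
    resample_path,
    sample_image,
    swath_coordinates,
)
from .errors import NoAISDetectedError, ValidationError
from .io import ImageStack, PathAnnotation


@dataclass
class LineProfile:
    """Intensity samples every ``step_um`` along one path, arclength 0 at the
    somatic end."""

    cell_id: str
    channel: str
    step_um: float
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.step_um > 0:
            raise ValidationError("step_um must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError("profile needs >= 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("profile values must be finite")

    @property
    def arclengths_um(self) -> np.ndarray:
        return np.arange(self.values.size) * self.step_um

    @property
    def length_um(self) -> float:
        return (self.values.size - 1) * self.step_um


@dataclass
class AISStart:
    cell_id: str
    start_um: float
    smoothing_window_um: float = 1.0
    threshold_fraction: float = 0.30
    at_origin: bool = False  # maximum already at arclength 0 (flagged, not fatal)


@dataclass
class AlignedProfileSet:
    """Profiles on a common axis relative to the AIS start (negative = somatic
    side). Positions covered by fewer than ``min_cells`` cells are dropped."""

    axis_um: np.ndarray  # (P,)
    values: np.ndarray  # (n_cells, P), NaN where a cell does not cover a position
    cell_ids: list[str]
    replicates: list[str]
    min_cells: int
    mean: np.ndarray = field(init=False)  # replicate-weighted mean per position
    sd: np.ndarray = field(init=False)  # SD across replicate means
    n: np.ndarray = field(init=False)  # total cells covering each position

    def __post_init__(self):
        import warnings

        reps = np.asarray(self.replicates)
        self.n = np.sum(~np.isnan(self.values), axis=0)
        rep_means = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # empty replicate slices -> NaN
            for rep in dict.fromkeys(self.replicates):
                block = self.values[reps == rep]
                rep_means.append(np.nanmean(block, axis=0))
            rep_means = np.array(rep_means)  # (R, P); NaN where replicate has no cell
            self.mean = np.nanmean(rep_means, axis=0)
            self.sd = np.nanstd(rep_means, axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position_um": self.axis_um, "mean": self.mean, "sd": self.sd, "n": self.n}
        )


def extract_profile(
    stack: ImageStack,
    channel: str,
    path: PathAnnotation,
    width_um: float | None = None,
    step_um: float | None = None,
) -> LineProfile:
    """Bilinear line profile along ``path``, averaged across ``width_um``
    perpendicular to the local tangent.

    Defaults follow the common plot-profile convention: step = pixel pitch,
    width = 3 pixels. Z is assumed already collapsed (max projection).
    """
    img = stack.channel(channel)
    if img.ndim == 3:  # time-lapse: profiles are defined per frame elsewhere
        raise ValidationError("extract_profile expects a single-frame stack")
    step_um = step_um or stack.pixel_size_um
    width_um = width_um if width_um is not None else 3 * stack.pixel_size_um
    pts, normals, arcs = resample_path(path.points_px, stack.pixel_size_um, step_um)
    offs = perpendicular_offsets(width_um, stack.pixel_size_um)
    coords = swath_coordinates(pts, normals, offs, stack.pixel_size_um)
    check_inside(pts[:, None, :], stack.shape_yx, what=f"path for {path.cell_id}")
    vals = sample_image(img, coords).mean(axis=1)
    return LineProfile(path.cell_id, channel, step_um, vals)


def sliding_mean(profile: LineProfile, window_um: float = 1.0) -> LineProfile:
    """Centred boxcar mean; edge windows shrink to the available support."""
    if window_um < profile.step_um:
        raise ValidationError("window_um must be at least one sample step")
    half = int(np.floor(window_um / (2 * profile.step_um)))
    kernel = np.ones(2 * half + 1)
    num = np.convolve(profile.values, kernel, mode="same")
    den = np.convolve(np.ones_like(profile.values), kernel, mode="same")
    return LineProfile(profile.cell_id, profile.channel, profile.step_um, num / den)


def detect_ais_start(
    profile: LineProfile,
    threshold_fraction: float = 0.30,
    window_um: float = 1.0,
) -> AISStart:
    """First arclength where the sliding-mean profile reaches
    ``threshold_fraction`` of its maximum."""
    smooth = sliding_mean(profile, window_um).values
    peak = smooth.max()
    if peak <= 0:
        raise NoAISDetectedError(f"no AIS signal in profile for {profile.cell_id}")
    idx = int(np.argmax(smooth >= threshold_fraction * peak))
    return AISStart(
        cell_id=profile.cell_id,
        start_um=idx * profile.step_um,
        smoothing_window_um=window_um,
        threshold_fraction=threshold_fraction,
        at_origin=idx == 0,
    )


def binary_presence_profile(
    stack: ImageStack,
    mask: np.ndarray,
    path: PathAnnotation,
    width_um: float | None = None,
    step_um: float | None = None,
) -> LineProfile:
    """Presence (0/1) along the path: 1 where any mask pixel within
    ``width_um`` of the path sample is foreground."""
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(np.unique(mask), (0, 1)).all():
        raise ValidationError("mask must be binary")
    mask = mask.astype(bool)
    step_um = step_um or stack.pixel_size_um
    width_um = width_um if width_um is not None else 3 * stack.pixel_size_um
    pts, normals, _ = resample_path(path.points_px, stack.pixel_size_um, step_um)
    offs = perpendicular_offsets(width_um, stack.pixel_size_um)
    coords = swath_coordinates(pts, normals, offs, stack.pixel_size_um)
    vals = sample_image(mask.astype(float), coords, order=0).max(axis=1)
    return LineProfile(path.cell_id, "presence", step_um, (vals > 0).astype(float))


def align_and_average(
    profiles: list[LineProfile],
    starts: list[AISStart],
    replicates: list[str],
    min_cells: int = 3,
) -> AlignedProfileSet:
    """Align per-cell profiles to their AIS starts and average with the
    replicate-weighted mean. Positions covered by < ``min_cells`` cells in
    total are dropped."""
    if not (len(profiles) == len(starts) == len(replicates)):
        raise ValidationError("profiles, starts and replicates must have equal length")
    step = profiles[0].step_um
    if any(abs(p.step_um - step) > 1e-9 for p in profiles):
        raise ValidationError("all profiles must share the same step_um")
    # integer grid offsets of each cell's samples relative to its AIS start
    shifts = [int(round(st.start_um / step)) for st in starts]
    lo = min(-sh for sh in shifts)
    hi = max(p.values.size - 1 - sh for p, sh in zip(profiles, shifts))
    axis = np.arange(lo, hi + 1) * step
    values = np.full((len(profiles), axis.size), np.nan)
    for i, (p, sh) in enumerate(zip(profiles, shifts)):
        start_col = -sh - lo
        values[i, start_col : start_col + p.values.size] = p.values
    n = np.sum(~np.isnan(values), axis=0)
    keep_cols = n >= min_cells
    return AlignedProfileSet(
        axis_um=axis[keep_cols],
        values=values[:, keep_cols],
        cell_ids=[p.cell_id for p in profiles],
        replicates=list(replicates),
        min_cells=min_cells,
    )


DEFAULT_WINDOWS = {"proximal": (-5.0, 5.0), "central": (10.0, 20.0), "distal": (25.0, 35.0)}


def make_windows(offset_um: float = 15.0, span_um: float = 10.0) -> dict[str, tuple[float, float]]:
    """Three 10 µm windows around the AIS start with a fixed equal spacing:
    proximal centred on the start, central and distal shifted by ``offset_um``
    and ``2*offset_um``."""
    half = span_um / 2
    return {
        "proximal": (-half, half),
        "central": (-half + offset_um, half + offset_um),
        "distal": (-half + 2 * offset_um, half + 2 * offset_um),
    }


def region_means(
    aligned: AlignedProfileSet,
    windows: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-replicate mean (of per-cell means) inside each named window.

    Returns a tidy frame with columns window, replicate, mean, n_cells.
    """
    windows = windows or DEFAULT_WINDOWS
    rows = []
    reps = np.asarray(aligned.replicates)
    for name, (a, b) in windows.items():
        cols = (aligned.axis_um >= a - 1e-9) & (aligned.axis_um <= b + 1e-9)
        if not cols.any():
            raise ValidationError(f"window {name!r} [{a}, {b}] outside the aligned axis")
        block = aligned.values[:, cols]
        with np.errstate(invalid="ignore"):
            cell_means = np.nanmean(block, axis=1)
        for rep in dict.fromkeys(aligned.replicates):
            cm = cell_means[(reps == rep) & ~np.isnan(cell_means)]
            rows.append(
                {
                    "window": name,
                    "replicate": rep,
                    "mean": float(np.mean(cm)) if cm.size else np.nan,
                    "n_cells": int(cm.size),
                }
            )
    return pd.DataFrame(rows)


def window_grand_means(per_replicate: pd.DataFrame) -> pd.Series:
    """Replicate-weighted grand mean per window (mean of replicate means)."""
    return per_replicate.groupby("window")["mean"].mean()
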