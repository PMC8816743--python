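"""Image stacks, annotations and measurement tables.

Images are TIFF files with axes ``[T?][C][Y][X]``; axis order and physical
metadata are stored in the TIFF's shaped metadata on write and recovered on
read (explicit keyword arguments override / supply missing metadata).
Annotations travel in a small JSON dialect::

    {"cells": [{"cell_id": "...",
                "paths": [{"role": "axon", "points_px": [[x, y], ...]}],
                "rois":  [{"label": "soma", "polygon_px": [[x, y], ...]}]}]}

Measurement tables are tidy CSVs with the fixed column order
``cell_id, replicate_id, condition, metric_name, value, units``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from ._geometry import polyline_arclength_um
from .errors import ConfigurationError, ValidationError

MEASUREMENT_COLUMNS = ["cell_id", "replicate_id", "condition", "metric_name", "value", "units"]


@dataclass
class ImageStack:
    """Multi-channel (optionally multi-frame) image with physical calibration.

    ``pixels`` has shape ``(C, Y, X)`` or ``(T, C, Y, X)``; the pixel grid is
    isotropic with pitch ``pixel_size_um``.
    """

    pixels: np.ndarray
    channel_names: list[str]
    pixel_size_um: float
    frame_interval_s: float | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (3, 4):
            raise ValidationError("pixels must be (C, Y, X) or (T, C, Y, X)")
        if len(self.channel_names) != self.pixels.shape[-3]:
            raise ValidationError("channel_names length must equal the channel axis")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")
        if self.has_time and self.frame_interval_s is None:
            raise ValidationError("time axis present but frame_interval_s missing")
        if self.frame_interval_s is not None and not self.frame_interval_s > 0:
            raise ValidationError("frame_interval_s must be positive")

    @property
    def has_time(self) -> bool:
        return self.pixels.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0] if self.has_time else 1

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[-2], self.pixels.shape[-1]

    def channel(self, name: str) -> np.ndarray:
        """The 2D (or 3D ``(T, Y, X)``) plane for one named channel."""
        try:
            c = self.channel_names.index(name)
        except ValueError:
            raise ValidationError(f"no channel named {name!r}; have {self.channel_names}")
        return self.pixels[:, c] if self.has_time else self.pixels[c]


@dataclass
class PathAnnotation:
    """Ordered polyline from the somatic end outward along one neurite."""

    cell_id: str
    role: str  # "axon" | "dendrite"
    points_px: np.ndarray  # (N, 2) of (x, y)

    def __post_init__(self):
        self.points_px = np.asarray(self.points_px, dtype=float)
        if self.role not in ("axon", "dendrite"):
            raise ValidationError(f"role must be axon or dendrite, got {self.role!r}")
        if self.points_px.ndim != 2 or self.points_px.shape[0] < 2 or self.points_px.shape[1] != 2:
            raise ValidationError(f"path for {self.cell_id} needs >= 2 (x, y) points")
        if np.any(np.all(np.diff(self.points_px, axis=0) == 0, axis=1)):
            raise ValidationError(f"path for {self.cell_id} has repeated consecutive points")

    def arclength_um(self, pixel_size_um: float) -> float:
        return float(polyline_arclength_um(self.points_px, pixel_size_um)[-1])


@dataclass
class RoiAnnotation:
    """Closed polygon region (soma, background or custom)."""

    cell_id: str
    label: str  # "soma" | "background" | "custom"
    polygon_px: np.ndarray  # (N, 2) of (x, y)

    def __post_init__(self):
        self.polygon_px = np.asarray(self.polygon_px, dtype=float)
        if self.label not in ("soma", "background", "custom"):
            raise ValidationError(f"roi label must be soma/background/custom, got {self.label!r}")
        if self.polygon_px.ndim != 2 or self.polygon_px.shape[0] < 3:
            raise ValidationError(f"roi for {self.cell_id} needs >= 3 vertices")
        poly = Polygon(self.polygon_px)
        if not poly.is_valid:
            raise ValidationError(f"roi for {self.cell_id} is self-intersecting or degenerate")
        if not poly.area > 0:
            raise ValidationError(f"roi for {self.cell_id} has zero area")

    def shapely(self) -> Polygon:
        return Polygon(self.polygon_px)


@dataclass
class CellAnnotations:
    """All annotations for one image: polyline paths and polygon ROIs per cell."""

    paths: list[PathAnnotation] = field(default_factory=list)
    rois: list[RoiAnnotation] = field(default_factory=list)

    def path(self, cell_id: str, role: str = "axon") -> PathAnnotation:
        for p in self.paths:
            if p.cell_id == cell_id and p.role == role:
                return p
        raise ValidationError(f"no {role} path for cell {cell_id!r}")

    def roi(self, cell_id: str, label: str) -> RoiAnnotation:
        for r in self.rois:
            if r.cell_id == cell_id and r.label == label:
                return r
        raise ValidationError(f"no {label} roi for cell {cell_id!r}")

    @property
    def cell_ids(self) -> list[str]:
        seen: list[str] = []
        for p in self.paths:
            if p.cell_id not in seen:
                seen.append(p.cell_id)
        return seen


# ---------------------------------------------------------------------------
# image I/O


def write_image_stack(stack: ImageStack, path) -> None:
    meta = {
        "axes": "TCYX" if stack.has_time else "CYX",
        "pixel_size_um": stack.pixel_size_um,
        "channel_names": list(stack.channel_names),
    }
    if stack.frame_interval_s is not None:
        meta["frame_interval_s"] = stack.frame_interval_s
    tifffile.imwrite(path, stack.pixels, metadata=meta, photometric="minisblack")


def read_image_stack(
    path,
    *,
    pixel_size_um: float | None = None,
    channel_names: Sequence[str] | None = None,
    axes: str | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a TIFF into an ``ImageStack``.

    Metadata written by :func:`write_image_stack` is honoured; for foreign
    TIFFs the keyword arguments declare axis order and calibration. A missing
    pixel size is a configuration error.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = {}
        if tf.shaped_metadata:
            meta = dict(tf.shaped_metadata[0])
    axes = axes or meta.get("axes")
    if axes is None:
        axes = {2: "YX", 3: "CYX", 4: "TCYX"}.get(arr.ndim)
    if axes is None or arr.ndim not in (2, 3, 4):
        raise ConfigurationError("cannot resolve image axes; pass axes= (e.g. 'CYX')")
    axes = axes.upper()
    if sorted(axes) != sorted(set(axes)) or len(axes) != arr.ndim:
        raise ConfigurationError(f"axes {axes!r} do not match array with {arr.ndim} dims")
    if set(axes) - set("TCYX"):
        raise ConfigurationError(f"unsupported axes {axes!r}; only T, C, Y, X are handled")
    order = [axes.index(a) for a in ("T", "C", "Y", "X") if a in axes]
    arr = np.transpose(arr, order)
    if "C" not in axes:  # promote to an explicit single-channel axis
        arr = np.expand_dims(arr, axis=-3)
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ConfigurationError("pixel_size_um not in metadata; pass pixel_size_um=")
    names = list(channel_names) if channel_names is not None else meta.get("channel_names")
    if names is None:
        names = [f"ch{i}" for i in range(arr.shape[-3])]
    interval = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    return ImageStack(arr, list(names), float(px), interval)


# ---------------------------------------------------------------------------
# annotation I/O


def annotations_to_dict(ann: CellAnnotations) -> dict:
    cells: dict[str, dict] = {}
    for p in ann.paths:
        cells.setdefault(p.cell_id, {"cell_id": p.cell_id, "paths": [], "rois": []})
        cells[p.cell_id]["paths"].append(
            {"role": p.role, "points_px": np.asarray(p.points_px).tolist()}
        )
    for r in ann.rois:
        cells.setdefault(r.cell_id, {"cell_id": r.cell_id, "paths": [], "rois": []})
        cells[r.cell_id]["rois"].append(
            {"label": r.label, "polygon_px": np.asarray(r.polygon_px).tolist()}
        )
    return {"cells": list(cells.values())}


def write_annotations(ann: CellAnnotations, path) -> None:
    Path(path).write_text(json.dumps(annotations_to_dict(ann), indent=1))


def read_annotations(path) -> CellAnnotations:
    """Read and validate the JSON annotation dialect."""
    doc = json.loads(Path(path).read_text())
    ann = CellAnnotations()
    seen_roles: set[tuple[str, str]] = set()
    for cell in doc.get("cells", []):
        cid = cell["cell_id"]
        for p in cell.get("paths", []):
            key = (cid, p["role"])
            if key in seen_roles:
                raise ValidationError(f"duplicate path for cell {cid!r} role {p['role']!r}")
            seen_roles.add(key)
            ann.paths.append(PathAnnotation(cid, p["role"], p["points_px"]))
        for r in cell.get("rois", []):
            ann.rois.append(RoiAnnotation(cid, r["label"], r["polygon_px"]))
    return ann


# ---------------------------------------------------------------------------
# measurement tables


def validate_measurements(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"measurement table missing columns {missing}")
    dup = table.duplicated(subset=["cell_id", "metric_name", "condition"])
    if dup.any():
        raise ValidationError("duplicate (cell_id, metric_name, condition) rows")
    return table[MEASUREMENT_COLUMNS]


def write_measurements(table: pd.DataFrame, path) -> None:
    validate_measurements(table).to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "replicate_id": str, "condition": str})
    if len(df):
        return validate_measurements(df)
    return df
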