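"""Polyline arclength utilities shared by profile extraction, rendering and kymographs.

Convention (used package-wide): pixel coordinates are 0-based, a pixel's centre
sits at its integer coordinate, points are (x, y), and arclength 0 is the first
path vertex (the somatic end). All physical distances are in micrometres and the
pixel grid is isotropic.
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ValidationError


def polyline_arclength_um(points_px: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Cumulative arclength (µm) at each vertex of an (N, 2) polyline in pixels."""
    pts = np.asarray(points_px, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1) * pixel_size_um
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_path(
    points_px: np.ndarray, pixel_size_um: float, step_um: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arclength.

    Returns ``(pts_px, normals, arclens_um)`` where ``pts_px`` is (M, 2) in
    (x, y) pixels, ``normals`` the (M, 2) unit normals (left of travel) and
    ``arclens_um`` the sampled arclengths starting at 0.
    """
    pts = np.asarray(points_px, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValidationError("path needs at least two points")
    s = polyline_arclength_um(pts, pixel_size_um)
    if np.any(np.diff(s) <= 0):
        raise ValidationError("consecutive path points must be distinct")
    total = s[-1]
    targets = np.arange(0.0, total + 0.5 * step_um, step_um)
    targets = targets[targets <= total + 1e-9]
    x = np.interp(targets, s, pts[:, 0])
    y = np.interp(targets, s, pts[:, 1])
    out = np.column_stack([x, y])
    # tangent via central differences on the resampled curve
    tang = np.gradient(out, axis=0)
    norm = np.linalg.norm(tang, axis=1)
    norm[norm == 0] = 1.0
    tang /= norm[:, None]
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    return out, normals, targets


def sample_image(
    image: np.ndarray, coords_xy: np.ndarray, order: int = 1
) -> np.ndarray:
    """Interpolate a 2D image at (x, y) pixel coordinates (bilinear by default)."""
    coords_xy = np.asarray(coords_xy, dtype=float)
    # map_coordinates wants (row, col) == (y, x)
    rc = np.stack([coords_xy[..., 1].ravel(), coords_xy[..., 0].ravel()])
    vals = map_coordinates(np.asarray(image, dtype=float), rc, order=order, mode="constant")
    return vals.reshape(coords_xy.shape[:-1])


def perpendicular_offsets(width_um: float, pixel_size_um: float, spacing_px: float = 0.5):
    """Symmetric offsets (µm) spanning ``width_um`` across a path, dense enough
    for an area-weighted average."""
    half = width_um / 2.0
    n = max(1, int(np.ceil(width_um / (spacing_px * pixel_size_um))))
    if n == 1:
        return np.array([0.0])
    return np.linspace(-half, half, n + 1)


def swath_coordinates(
    pts_px: np.ndarray, normals: np.ndarray, offsets_um: np.ndarray, pixel_size_um: float
) -> np.ndarray:
    """Coordinates (M, K, 2) of perpendicular sample points around each path point."""
    off_px = np.asarray(offsets_um) / pixel_size_um
    return pts_px[:, None, :] + off_px[None, :, None] * normals[:, None, :]


def check_inside(coords_xy: np.ndarray, shape_yx: tuple[int, int], what: str = "path") -> None:
    x = coords_xy[..., 0]
    y = coords_xy[..., 1]
    h, w = shape_yx
    bad = (x < -0.5) | (x > w - 0.5) | (y < -0.5) | (y > h - 0.5)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what} exits image bounds at sample index {tuple(int(i) for i in idx)}"
        )
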