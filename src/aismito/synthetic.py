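"""Synthetic fluorescence neuron scenes and time-lapse movies with ground truth.

The generator emulates the statistical structure of the study data: a soma
with dendrites and one axon; an AIS-marker channel ramping up at a defined
start point; punctate mitochondria, optionally enriched within the proximal
cluster window and depleted in the central AIS; somatodendritic MAP2 and TAU
channels with a configurable somatic-TAU fold-change; a volume channel with a
tapering width profile; and two-channel movies with a stationary
(photoconverted, red) proximal band plus scripted moving particles.

Everything downstream can be scored against the returned ground truth; the
same seed always yields bitwise-identical pixels.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, ValidationError
from .io import (
    CellAnnotations,
    ImageStack,
    PathAnnotation,
    RoiAnnotation,
    write_annotations,
    write_image_stack,
)

SCENE_CHANNELS = ["MAP2", "AIS", "MITO", "TAU", "VOL"]
MOVIE_CHANNELS = ["green", "red"]


@dataclass
class SceneConfig:
    """All knobs of the scene generator (lengths in µm, intensities in counts).

    The defaults encode the study conditions the generator emulates: an AIS
    starting ~5 µm from the soma with a ~30 µm extent, a mitochondrial
    linear density giving a binary presence fraction near 0.3 along an
    unremarkable axon stretch, and — when ``cluster_present`` — a proximal
    cluster of brighter mitochondria within ±7.5 µm of the AIS start followed
    by a strongly depleted central AIS.
    """

    pixel_size_um: float = 0.2
    image_size_px: tuple[int, int] = (384, 704)  # (Y, X)
    soma_radius_um: float = 8.0
    n_dendrites: int = 3
    dendrite_length_um: float = 25.0
    axon_length_um: float = 80.0
    ais_start_um: float = 5.0
    ais_length_um: float = 30.0
    cluster_present: bool = True
    cluster_window_um: float = 7.5
    cluster_mito_count: int = 6
    cluster_amplitude_gain: float = 3.0
    central_depletion_factor: float = 0.2
    baseline_mito_density: float = 0.25  # puncta per µm of neurite
    mito_sigma_um: float = 0.45
    mito_amplitude: float = 120.0
    mito_soma_level: float = 40.0
    tau_somatic_fold: float = 1.0
    tau_axon_ref: float = 100.0
    map2_soma_level: float = 400.0
    map2_dendrite_level: float = 300.0
    ais_plateau_level: float = 300.0
    ais_ramp_um: float = 1.0
    vol_level: float = 200.0
    axon_radius_base_um: float = 0.75
    axon_radius_tip_um: float = 0.35
    curvature_sd_rad: float = 0.04
    heading_jitter_rad: float = 0.12
    background_level: float = 20.0
    poisson_scale: float = 1.0  # 0 disables shot noise
    gaussian_sd: float = 2.0  # 0 disables read noise
    bleach_tau_s: float | None = None  # optional global exponential photobleaching
    seed: int = 0

    def __post_init__(self):
        for name in (
            "pixel_size_um",
            "soma_radius_um",
            "axon_length_um",
            "ais_length_um",
            "cluster_window_um",
            "mito_sigma_um",
        ):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.central_depletion_factor <= 1:
            raise ValidationError("central_depletion_factor must lie in [0, 1]")
        if self.tau_somatic_fold < 0:
            raise ValidationError("tau_somatic_fold must be >= 0")
        if self.ais_start_um < 0:
            raise ValidationError("ais_start_um must be >= 0")


@dataclass
class ScriptedEvent:
    """One scripted trafficking particle on the axon distance axis."""

    t_start_s: float
    x_start_um: float
    velocity_um_per_s: float
    duration_s: float
    origin: str  # "cluster" | "other"
    channel: str  # "red" | "green"

    def __post_init__(self):
        if self.velocity_um_per_s == 0:
            raise ValidationError("moving events need a non-zero velocity")
        if self.origin not in ("cluster", "other"):
            raise ValidationError("origin must be cluster or other")
        if self.channel not in MOVIE_CHANNELS:
            raise ValidationError("channel must be red or green")

    def position_um(self, t_s: float) -> float:
        return self.x_start_um + self.velocity_um_per_s * (t_s - self.t_start_s)

    @property
    def t_end_s(self) -> float:
        return self.t_start_s + self.duration_s

    @property
    def x_end_um(self) -> float:
        return self.position_um(self.t_end_s)


@dataclass
class EventScript:
    events: list[ScriptedEvent] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Generative truth sufficient to score every downstream estimator."""

    ais_start_um: float
    category: str  # "+" if a cluster was generated, "-" otherwise
    tau_somatic_fold: float
    soma_center_px: tuple[float, float]
    puncta: list[dict] = field(default_factory=list)  # structure, s_um, amplitude, x/y px, in_cluster
    events: list[dict] = field(default_factory=list)  # scripted events incl. clipped flag
    cluster_span_um: tuple[float, float] | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["soma_center_px"] = tuple(d["soma_center_px"])
        if d.get("cluster_span_um") is not None:
            d["cluster_span_um"] = tuple(d["cluster_span_um"])
        return cls(**d)


# ---------------------------------------------------------------------------
# geometry


def _random_walk_path(
    start_xy: np.ndarray,
    heading: float,
    length_um: float,
    pixel_size_um: float,
    curvature_sd: float,
    rng: np.random.Generator,
    step_um: float = 1.0,
) -> np.ndarray:
    """Smooth polyline of ``length_um`` with bounded heading drift (px coords)."""
    n = int(np.ceil(length_um / step_um))
    dthetas = rng.normal(0.0, curvature_sd, n)
    thetas = heading + np.clip(np.cumsum(dthetas), -0.45, 0.45)
    steps = (step_um / pixel_size_um) * np.column_stack([np.cos(thetas), np.sin(thetas)])
    return np.vstack([start_xy, start_xy + np.cumsum(steps, axis=0)])


@dataclass
class _Geometry:
    soma_center_px: np.ndarray
    axon_px: np.ndarray  # polyline, vertex spacing 1 µm, starts at soma edge
    dendrites_px: list[np.ndarray]


def _build_geometry(cfg: SceneConfig, rng: np.random.Generator) -> _Geometry:
    """Draw a soma + neurite layout; random-walk draws that wander off the
    canvas are redrawn (deterministically) before the config is declared
    infeasible."""
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um
    margin = (cfg.axon_radius_base_um + 4 * cfg.mito_sigma_um) / px
    for _attempt in range(25):
        cx = (cfg.dendrite_length_um + cfg.soma_radius_um + 4.0) / px
        cy = h / 2 + rng.uniform(-3, 3) / px
        center = np.array([cx, cy])
        heading = rng.uniform(-cfg.heading_jitter_rad, cfg.heading_jitter_rad)
        start = center + (cfg.soma_radius_um / px) * np.array(
            [np.cos(heading), np.sin(heading)]
        )
        axon = _random_walk_path(
            start, heading, cfg.axon_length_um, px, cfg.curvature_sd_rad, rng
        )
        dendrites = []
        if cfg.n_dendrites:
            base = np.linspace(0.55 * np.pi, 1.45 * np.pi, cfg.n_dendrites)
            for ang in base + rng.uniform(-0.15, 0.15, cfg.n_dendrites):
                dstart = center + (cfg.soma_radius_um / px) * np.array(
                    [np.cos(ang), np.sin(ang)]
                )
                dendrites.append(
                    _random_walk_path(
                        dstart, ang, cfg.dendrite_length_um, px, cfg.curvature_sd_rad, rng
                    )
                )
        ok = True
        for pts in [axon, *dendrites, center[None, :]]:
            if (
                pts[:, 0].min() < margin
                or pts[:, 0].max() > w - 1 - margin
                or pts[:, 1].min() < margin
                or pts[:, 1].max() > h - 1 - margin
            ):
                ok = False
                break
        if ok:
            return _Geometry(center, axon, dendrites)
    raise ConfigurationError(
        "geometry does not fit image_size_px; enlarge the image or shorten neurites"
    )


def _dense_samples(polyline_px: np.ndarray, pixel_size_um: float, spacing_px: float = 0.4):
    """(points_px, arclengths_um) resampled densely along a polyline."""
    seg = np.linalg.norm(np.diff(polyline_px, axis=0), axis=1)
    s_px = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(0.0, s_px[-1], spacing_px)
    x = np.interp(targets, s_px, polyline_px[:, 0])
    y = np.interp(targets, s_px, polyline_px[:, 1])
    return np.column_stack([x, y]), targets * pixel_size_um


def _nearest_structure_maps(cfg: SceneConfig, geom: _Geometry):
    """Per-pixel nearest neurite sample: structure id (0 axon, 1.. dendrites),
    arclength (µm) and distance (µm)."""
    pts_list, s_list, id_list = [], [], []
    for i, poly in enumerate([geom.axon_px, *geom.dendrites_px]):
        p, s = _dense_samples(poly, cfg.pixel_size_um)
        pts_list.append(p)
        s_list.append(s)
        id_list.append(np.full(len(s), i))
    pts = np.vstack(pts_list)
    s = np.concatenate(s_list)
    ids = np.concatenate(id_list)
    h, w = cfg.image_size_px
    ys, xs = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    # pixels further than the widest tube radius can never be inside a neurite
    r_ub = 1.5 * cfg.axon_radius_base_um / cfg.pixel_size_um + 2.0
    dist_px, idx = cKDTree(pts).query(pix, distance_upper_bound=r_ub, workers=-1)
    shape = (h, w)
    outside = idx == len(s)
    idx = np.where(outside, 0, idx)
    struct = np.where(outside, -1, ids[idx]).reshape(shape)
    s_um = np.where(outside, 0.0, s[idx]).reshape(shape)
    dist_um = np.where(outside, np.inf, dist_px * cfg.pixel_size_um).reshape(shape)
    return struct, s_um, dist_um


def _axon_radius_um(cfg: SceneConfig, s_um: np.ndarray) -> np.ndarray:
    frac = np.clip(s_um / cfg.axon_length_um, 0, 1)
    return cfg.axon_radius_base_um + (cfg.axon_radius_tip_um - cfg.axon_radius_base_um) * frac


def _dendrite_radius_um(cfg: SceneConfig, s_um: np.ndarray) -> np.ndarray:
    frac = np.clip(s_um / max(cfg.dendrite_length_um, 1e-9), 0, 1)
    return 0.9 * cfg.axon_radius_base_um * (1 - 0.6 * frac)


def _ais_profile(cfg: SceneConfig, s_um: np.ndarray) -> np.ndarray:
    """0 before the start, linear ramp over ``ais_ramp_um``, plateau over the
    AIS extent, then exponential decay."""
    s0, ramp, plateau = cfg.ais_start_um, cfg.ais_ramp_um, cfg.ais_plateau_level
    out = np.zeros_like(s_um, dtype=float)
    rising = (s_um >= s0) & (s_um < s0 + ramp)
    out[rising] = plateau * (s_um[rising] - s0) / ramp
    flat = (s_um >= s0 + ramp) & (s_um <= s0 + cfg.ais_length_um)
    out[flat] = plateau
    tail = s_um > s0 + cfg.ais_length_um
    out[tail] = plateau * np.exp(-(s_um[tail] - s0 - cfg.ais_length_um) / 5.0)
    return out


# ---------------------------------------------------------------------------
# puncta


def _stamp_punctum(canvas: np.ndarray, x: float, y: float, amp: float, sigma_px: float):
    h, w = canvas.shape
    r = int(np.ceil(4 * sigma_px))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] += amp * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma_px**2)
    )


def _punctum_xy(polyline_px, pixel_size_um, s_um, offset_um, rng=None):
    seg = np.linalg.norm(np.diff(polyline_px, axis=0), axis=1) * pixel_size_um
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s_um = min(s_um, arc[-1])
    x = np.interp(s_um, arc, polyline_px[:, 0])
    y = np.interp(s_um, arc, polyline_px[:, 1])
    i = min(np.searchsorted(arc, s_um), len(polyline_px) - 1)
    tang = polyline_px[i] - polyline_px[i - 1]
    tang = tang / max(np.linalg.norm(tang), 1e-9)
    normal = np.array([-tang[1], tang[0]])
    off_px = offset_um / pixel_size_um
    return x + off_px * normal[0], y + off_px * normal[1]


def _sample_axon_puncta(cfg: SceneConfig, rng: np.random.Generator) -> list[dict]:
    """Baseline Poisson puncta along the axon, centrally depleted and with an
    amplified proximal cluster when ``cluster_present``."""
    L = cfg.axon_length_um
    s0 = cfg.ais_start_um
    puncta = []
    n_base = rng.poisson(cfg.baseline_mito_density * L)
    positions = np.sort(rng.uniform(0, L, n_base))
    central = (s0 + cfg.cluster_window_um, s0 + cfg.ais_length_um)
    keep = np.ones(n_base, dtype=bool)
    if cfg.cluster_present:
        in_central = (positions > central[0]) & (positions <= central[1])
        keep[in_central] = rng.uniform(size=in_central.sum()) < cfg.central_depletion_factor
    for s in positions[keep]:
        amp = cfg.mito_amplitude * float(np.clip(rng.normal(1.0, 0.12), 0.6, 1.5))
        puncta.append({"structure": "axon", "s_um": float(s), "amplitude": amp, "in_cluster": False})
    if cfg.cluster_present:
        lo = max(0.0, s0 - cfg.cluster_window_um)
        hi = min(L, s0 + cfg.cluster_window_um)
        for s in np.sort(rng.uniform(lo, hi, cfg.cluster_mito_count)):
            amp = cfg.mito_amplitude * cfg.cluster_amplitude_gain * float(
                np.clip(rng.normal(1.0, 0.12), 0.6, 1.5)
            )
            puncta.append(
                {"structure": "axon", "s_um": float(s), "amplitude": amp, "in_cluster": True}
            )
    return puncta


def _apply_noise(img: np.ndarray, cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    out = img + cfg.background_level
    if cfg.poisson_scale > 0:
        out = rng.poisson(out / cfg.poisson_scale).astype(float) * cfg.poisson_scale
    if cfg.gaussian_sd > 0:
        out = out + rng.normal(0.0, cfg.gaussian_sd, out.shape)
    return np.clip(out, 0, None)


# ---------------------------------------------------------------------------
# single-frame scenes


def _background_roi(cfg: SceneConfig, signal: np.ndarray) -> RoiAnnotation:
    """A 16x16 px background square in the emptiest image corner."""
    h, w = signal.shape
    m, k = 4, 16
    corners = {
        (m, m): signal[m : m + k, m : m + k].sum(),
        (w - m - k, m): signal[m : m + k, w - m - k : w - m].sum(),
        (m, h - m - k): signal[h - m - k : h - m, m : m + k].sum(),
        (w - m - k, h - m - k): signal[h - m - k : h - m, w - m - k : w - m].sum(),
    }
    x0, y0 = min(corners, key=corners.get)
    poly = [[x0, y0], [x0 + k, y0], [x0 + k, y0 + k], [x0, y0 + k]]
    return RoiAnnotation("cell0", "background", poly)


def generate_scene(
    config: SceneConfig, cell_id: str = "cell0"
) -> tuple[ImageStack, GroundTruth, CellAnnotations]:
    """Render one five-channel scene (MAP2, AIS, MITO, TAU, VOL) with ground
    truth and annotations (axon path, one dendrite path, soma + background ROI)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    geom = _build_geometry(cfg, rng)
    struct_id, s_map, dist_map = _nearest_structure_maps(cfg, geom)
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um

    ys, xs = np.mgrid[0:h, 0:w]
    soma = ((xs - geom.soma_center_px[0]) ** 2 + (ys - geom.soma_center_px[1]) ** 2) <= (
        cfg.soma_radius_um / px
    ) ** 2
    in_axon = (struct_id == 0) & (dist_map <= _axon_radius_um(cfg, s_map)) & ~soma
    in_dend = (struct_id > 0) & (dist_map <= _dendrite_radius_um(cfg, s_map)) & ~soma

    map2 = np.zeros((h, w))
    map2[in_dend] = cfg.map2_dendrite_level
    map2[in_axon] = cfg.map2_dendrite_level * np.exp(-s_map[in_axon] / 4.0)
    map2[soma] = cfg.map2_soma_level

    ais = np.zeros((h, w))
    ais[in_axon] = _ais_profile(cfg, s_map[in_axon])

    tau = np.zeros((h, w))
    tau[in_dend] = 0.3 * cfg.tau_axon_ref
    tau[in_axon] = cfg.tau_axon_ref
    tau[soma] = cfg.tau_axon_ref * cfg.tau_somatic_fold

    vol = np.zeros((h, w))
    vol[soma | in_axon | in_dend] = cfg.vol_level

    mito = np.zeros((h, w))
    mito[soma] = cfg.mito_soma_level
    sigma_px = cfg.mito_sigma_um / px
    puncta = _sample_axon_puncta(cfg, rng)
    for i, poly in enumerate(geom.dendrites_px):
        n = rng.poisson(cfg.baseline_mito_density * cfg.dendrite_length_um)
        for s in np.sort(rng.uniform(0, cfg.dendrite_length_um, n)):
            amp = cfg.mito_amplitude * float(np.clip(rng.normal(1.0, 0.12), 0.6, 1.5))
            puncta.append(
                {"structure": f"dendrite{i}", "s_um": float(s), "amplitude": amp, "in_cluster": False}
            )
    polylines = {"axon": geom.axon_px, **{f"dendrite{i}": d for i, d in enumerate(geom.dendrites_px)}}
    for p in puncta:
        offset = rng.uniform(-0.3, 0.3)
        x, y = _punctum_xy(polylines[p["structure"]], px, p["s_um"], offset)
        p["x_px"], p["y_px"] = float(x), float(y)
        _stamp_punctum(mito, x, y, p["amplitude"], sigma_px)

    channels = np.stack([map2, ais, mito, tau, vol])
    noisy = np.stack([_apply_noise(c, cfg, rng) for c in channels]).astype(np.float32)
    stack = ImageStack(noisy, list(SCENE_CHANNELS), px)

    ann = CellAnnotations()
    ann.paths.append(PathAnnotation(cell_id, "axon", geom.axon_px))
    if geom.dendrites_px:
        ann.paths.append(PathAnnotation(cell_id, "dendrite", geom.dendrites_px[0]))
    angles = np.linspace(0, 2 * np.pi, 25)[:-1]
    circle = geom.soma_center_px + (cfg.soma_radius_um / px) * np.column_stack(
        [np.cos(angles), np.sin(angles)]
    )
    ann.rois.append(RoiAnnotation(cell_id, "soma", circle))
    bg = _background_roi(cfg, channels.sum(axis=0))
    bg.cell_id = cell_id
    ann.rois.append(bg)

    gt = GroundTruth(
        ais_start_um=cfg.ais_start_um,
        category="+" if cfg.cluster_present else "-",
        tau_somatic_fold=cfg.tau_somatic_fold,
        soma_center_px=(float(geom.soma_center_px[0]), float(geom.soma_center_px[1])),
        puncta=puncta,
        cluster_span_um=(
            max(0.0, cfg.ais_start_um - cfg.cluster_window_um),
            cfg.ais_start_um + cfg.cluster_window_um,
        )
        if cfg.cluster_present
        else None,
    )
    return stack, gt, ann


# ---------------------------------------------------------------------------
# time-lapse movies


def generate_timelapse(
    config: SceneConfig,
    script: EventScript,
    duration_s: float,
    interval_s: float,
) -> tuple[ImageStack, GroundTruth, CellAnnotations]:
    """Two-channel (green/red) movie along the axon.

    Stationary content: baseline green puncta along the axon and — when
    ``cluster_present`` — the photoconverted red band at the cluster.
    Each scripted event renders as a punctum moving at its velocity in its
    channel; an event that exits the axon extent mid-run is clipped and
    flagged in the ground truth.
    """
    cfg = config
    if interval_s <= 0 or duration_s <= 0:
        raise ValidationError("duration_s and interval_s must be positive")
    rng = np.random.default_rng(cfg.seed)
    geom = _build_geometry(cfg, rng)
    h, w = cfg.image_size_px
    px = cfg.pixel_size_um
    sigma_px = cfg.mito_sigma_um / px
    span = (
        max(0.0, cfg.ais_start_um - cfg.cluster_window_um),
        cfg.ais_start_um + cfg.cluster_window_um,
    )

    # stationary structures
    static_green = []
    n = rng.poisson(cfg.baseline_mito_density * cfg.axon_length_um)
    for s in np.sort(rng.uniform(0, cfg.axon_length_um, n)):
        amp = cfg.mito_amplitude * float(np.clip(rng.normal(1.0, 0.12), 0.6, 1.5))
        static_green.append((float(s), amp))
    static_red = []
    if cfg.cluster_present:
        for s in np.sort(rng.uniform(span[0], span[1], cfg.cluster_mito_count)):
            amp = cfg.mito_amplitude * cfg.cluster_amplitude_gain * float(
                np.clip(rng.normal(1.0, 0.12), 0.6, 1.5)
            )
            static_red.append((float(s), amp))

    gt_events = []
    for ev in script.events:
        if ev.origin == "cluster":
            if ev.channel != "red" or not (span[0] - 1e-9 <= ev.x_start_um <= span[1] + 1e-9):
                raise ValidationError(
                    "cluster-origin events must be red and start inside the cluster window"
                )
        if ev.t_start_s < 0 or ev.t_end_s > duration_s + 1e-9:
            raise ValidationError("scripted event lies outside the movie duration")
        clipped = not (0 <= ev.x_end_um <= cfg.axon_length_um)
        gt_events.append({**dataclasses.asdict(ev), "clipped": bool(clipped)})

    times = np.arange(0.0, duration_s + 1e-9, interval_s)
    frames = np.zeros((len(times), 2, h, w), dtype=float)
    base = {"green": np.zeros((h, w)), "red": np.zeros((h, w))}
    for s, amp in static_green:
        x, y = _punctum_xy(geom.axon_px, px, s, 0.0)
        _stamp_punctum(base["green"], x, y, amp, sigma_px)
    for s, amp in static_red:
        x, y = _punctum_xy(geom.axon_px, px, s, 0.0)
        _stamp_punctum(base["red"], x, y, amp, sigma_px)

    for ti, t in enumerate(times):
        chans = {k: v.copy() for k, v in base.items()}
        for ev in script.events:
            if ev.t_start_s - 1e-9 <= t <= ev.t_end_s + 1e-9:
                s = np.clip(ev.position_um(t), 0.0, cfg.axon_length_um)
                x, y = _punctum_xy(geom.axon_px, px, s, 0.0)
                _stamp_punctum(chans[ev.channel], x, y, cfg.mito_amplitude * 1.5, sigma_px)
        fade = np.exp(-t / cfg.bleach_tau_s) if cfg.bleach_tau_s else 1.0
        frames[ti, 0] = fade * chans["green"]
        frames[ti, 1] = fade * chans["red"]
    noisy = np.stack(
        [
            np.stack([_apply_noise(frames[ti, c], cfg, rng) for c in range(2)])
            for ti in range(len(times))
        ]
    ).astype(np.float32)
    stack = ImageStack(noisy, list(MOVIE_CHANNELS), px, frame_interval_s=interval_s)

    ann = CellAnnotations()
    ann.paths.append(PathAnnotation("cell0", "axon", geom.axon_px))
    gt = GroundTruth(
        ais_start_um=cfg.ais_start_um,
        category="+" if cfg.cluster_present else "-",
        tau_somatic_fold=cfg.tau_somatic_fold,
        soma_center_px=(float(geom.soma_center_px[0]), float(geom.soma_center_px[1])),
        events=gt_events,
        cluster_span_um=span,
    )
    return stack, gt, ann


def random_script(
    config: SceneConfig,
    n_events: int,
    duration_s: float,
    rng: np.random.Generator,
    p_cluster: float = 0.15,
    speed_range: tuple[float, float] = (0.25, 0.6),
    event_duration_range: tuple[float, float] = (20.0, 40.0),
    min_separation_um: float = 3.0,
    max_tries: int = 20000,
) -> EventScript:
    """A random script of non-crossing events that all overlap the cluster span
    (so every event "goes past the cluster"). Cluster-origin events are red
    and start inside the span; all others are green."""
    span = (
        max(0.0, config.ais_start_um - config.cluster_window_um),
        config.ais_start_um + config.cluster_window_um,
    )
    L = config.axon_length_um
    events: list[ScriptedEvent] = []

    def crosses(a: ScriptedEvent, b: ScriptedEvent) -> bool:
        if a.channel != b.channel:
            return False
        t0 = max(a.t_start_s, b.t_start_s)
        t1 = min(a.t_end_s, b.t_end_s)
        if t1 < t0:
            return False
        ts = np.linspace(t0, t1, 16)
        da = np.array([a.position_um(t) for t in ts])
        db = np.array([b.position_um(t) for t in ts])
        return bool(np.min(np.abs(da - db)) < min_separation_um)

    # origin and direction are committed up front so that placement rejections
    # cannot bias the cluster/other (or antero/retro) composition
    plan = []
    for _ in range(n_events):
        origin = "cluster" if rng.uniform() < p_cluster else "other"
        # cluster-origin movers head anterograde; others are ~60% anterograde
        antero = True if origin == "cluster" else bool(rng.uniform() < 0.6)
        plan.append((origin, antero))
    for origin, antero in plan:
        tries = 0
        while True:
            tries += 1
            if tries > max_tries:
                raise ConfigurationError(
                    "could not place non-overlapping events; lengthen the movie "
                    "or reduce n_events"
                )
            speed = rng.uniform(*speed_range)
            dur = rng.uniform(*event_duration_range)
            if origin == "cluster":
                channel = "red"
                x0 = rng.uniform(span[0] + 0.5, span[1] - 0.5)
                v = speed
            else:
                channel = "green"
                if antero:  # approaching the span from the soma side
                    x0 = rng.uniform(max(0.0, span[0] - 10.0), span[1] - 1.0)
                    v = speed
                else:  # retrograde, coming back from further down the axon
                    x0 = rng.uniform(span[0] + 1.0, min(L, span[1] + 10.0))
                    v = -speed
            t0 = rng.uniform(0.0, duration_s - dur)
            # keep the full run inside the axon extent and crossing the span
            x1 = x0 + v * dur
            if not (0.5 <= x1 <= L - 0.5):
                continue
            if min(x0, x1) > span[1] or max(x0, x1) < span[0]:
                continue  # run never overlaps the cluster span
            cand = ScriptedEvent(float(t0), float(x0), float(v), float(dur), origin, channel)
            if any(crosses(cand, e) for e in events):
                continue
            events.append(cand)
            break
    return EventScript(events)


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(
    config: SceneConfig,
    n_cells: int,
    cluster_fraction: float,
    seed: int,
    out_dir,
    n_replicates: int = 3,
) -> dict:
    """Write ``n_cells`` jittered scenes (images, annotations, ground truth) and
    a manifest. Exactly ``round(n_cells * cluster_fraction)`` cells carry the
    cluster; the assignment is a deterministic function of ``seed``."""
    if n_cells <= 0:
        raise ValidationError("n_cells must be >= 1")
    if not 0 <= cluster_fraction <= 1:
        raise ValidationError("cluster_fraction must lie in [0, 1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_cells * cluster_fraction))
    positive = np.zeros(n_cells, dtype=bool)
    positive[rng.permutation(n_cells)[:n_pos]] = True
    child_seeds = np.random.SeedSequence(seed).spawn(n_cells)
    manifest = {"seed": seed, "n_cells": n_cells, "cluster_fraction": cluster_fraction, "cells": []}
    for i in range(n_cells):
        jit = np.random.default_rng(child_seeds[i])
        cell_seed = int(jit.integers(0, 2**31 - 1))
        cfg = dataclasses.replace(
            config,
            ais_start_um=max(1.0, config.ais_start_um + jit.uniform(-1.5, 1.5)),
            soma_radius_um=config.soma_radius_um * jit.uniform(0.9, 1.1),
            axon_length_um=config.axon_length_um + jit.uniform(-5.0, 5.0),
            cluster_present=bool(positive[i]),
            seed=cell_seed,
        )
        cell_id = f"cell{i:03d}"
        stack, gt, ann = generate_scene(cfg, cell_id=cell_id)
        img_path = out_dir / f"{cell_id}.tif"
        ann_path = out_dir / f"{cell_id}.annotations.json"
        gt_path = out_dir / f"{cell_id}.truth.json"
        write_image_stack(stack, img_path)
        write_annotations(ann, ann_path)
        gt_path.write_text(gt.to_json())
        manifest["cells"].append(
            {
                "cell_id": cell_id,
                "replicate": f"rep{i % n_replicates}",
                "cluster_present": bool(positive[i]),
                "image": img_path.name,
                "annotations": ann_path.name,
                "ground_truth": gt_path.name,
            }
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def generate_presence_cohort(
    n_cells: int,
    p_proximal: float,
    p_central: float,
    p_other: float = 0.3,
    segment_um: float = 1.0,
    step_um: float = 0.5,
    start_um: float = 10.0,
    post_um: float = 35.0,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Binary presence profiles with known per-window presence probabilities.

    Presence is drawn independently per 1 µm segment: probability
    ``p_proximal`` in [-5, 5) around the AIS start, ``p_central`` in [10, 20)
    and ``p_other`` elsewhere. Returns ``(profiles, starts, replicates, truth)``
    with the per-window probabilities in ``truth``.
    """
    from .profiles import AISStart, LineProfile  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    profiles, starts, reps = [], [], []
    for i in range(n_cells):
        start = start_um + step_um * rng.integers(-4, 5)  # jitter on the sample grid
        rel = np.arange(0.0, start + post_um + 1e-9, step_um) - start
        seg_idx = np.floor(rel / segment_um).astype(int)
        uniq = np.unique(seg_idx)
        seg_vals = {}
        for k in uniq:
            centre = (k + 0.5) * segment_um
            if -5 <= centre < 5:
                p = p_proximal
            elif 10 <= centre < 20:
                p = p_central
            else:
                p = p_other
            seg_vals[k] = float(rng.uniform() < p)
        values = np.array([seg_vals[k] for k in seg_idx])
        cid = f"cell{i:03d}"
        profiles.append(LineProfile(cid, "presence", step_um, values))
        starts.append(AISStart(cid, float(start)))
        reps.append(f"rep{i % n_replicates}")
    truth = {"proximal": p_proximal, "central": p_central, "other": p_other}
    return profiles, starts, reps, truth


def generate_roi_drop_movie(
    n_frames: int = 75,
    interval_s: float = 6.0,
    drop_time_s: float = 60.0,
    drop_factor: float = 0.2,
    level: float = 200.0,
    image_size_px: tuple[int, int] = (96, 96),
    pixel_size_um: float = 0.3,
    background_level: float = 10.0,
    gaussian_sd: float = 0.0,
    bleach_tau_s: float | None = None,
    seed: int = 0,
) -> tuple[ImageStack, CellAnnotations]:
    """A minimal membrane-potential-style movie: two bright blobs; blob A's
    signal drops to ``drop_factor`` of its level at ``drop_time_s`` while blob
    B stays constant. Returns the movie plus ROI annotations A and B."""
    rng = np.random.default_rng(seed)
    h, w = image_size_px
    ys, xs = np.mgrid[0:h, 0:w]
    ca = (w * 0.3, h * 0.5)
    cb = (w * 0.7, h * 0.5)
    r = 0.12 * min(h, w)
    blob_a = ((xs - ca[0]) ** 2 + (ys - ca[1]) ** 2) <= r**2
    blob_b = ((xs - cb[0]) ** 2 + (ys - cb[1]) ** 2) <= r**2
    frames = np.zeros((n_frames, 1, h, w))
    for t in range(n_frames):
        time_s = t * interval_s
        a_level = level * (drop_factor if time_s >= drop_time_s else 1.0)
        img = np.zeros((h, w))
        img[blob_a] = a_level
        img[blob_b] = level
        if bleach_tau_s:
            img *= np.exp(-time_s / bleach_tau_s)
        img += background_level
        if gaussian_sd > 0:
            img += rng.normal(0, gaussian_sd, img.shape)
        frames[t, 0] = np.clip(img, 0, None)
    stack = ImageStack(frames.astype(np.float32), ["TMRM"], pixel_size_um, frame_interval_s=interval_s)
    ann = CellAnnotations()
    square = lambda c: [
        [c[0] - r * 0.7, c[1] - r * 0.7],
        [c[0] + r * 0.7, c[1] - r * 0.7],
        [c[0] + r * 0.7, c[1] + r * 0.7],
        [c[0] - r * 0.7, c[1] + r * 0.7],
    ]
    ann.rois.append(RoiAnnotation("roiA", "custom", square(ca)))
    ann.rois.append(RoiAnnotation("roiB", "custom", square(cb)))
    return stack, ann
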