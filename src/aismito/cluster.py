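"""Per-cell classification of the AIS-mitochondria cluster and cohort summaries.

A cell is scored on three criteria: (1) mitochondria present in the proximal
AIS (±7.5 µm around the AIS start); (2) relative absence of mitochondria in
the central AIS; (3) visibly brighter mitochondria in the proximal AIS than
along the rest of the axon. Cells meeting 3 criteria are cluster (+), 2 are
(~), and <= 1 is (–). The cohort summary reports both the printed ratio
n_total / (n+ + 0.5 n~) and its reciprocal, the positive fraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import resample_path, sample_image, swath_coordinates
from .errors import InvalidCellError, ValidationError
from .io import ImageStack, PathAnnotation
from .profiles import AISStart, LineProfile


@dataclass
class ClusterCriteria:
    """Numeric thresholds behind the three (visually phrased) criteria.

    ``central_window_um`` is expressed relative to the AIS start and reuses
    the region-mean "central" window definition.
    """

    proximal_window_um: float = 7.5
    presence_min_fraction: float = 0.3  # criterion 1
    central_absence_max_ratio: float = 0.5  # criterion 2: central <= alpha * proximal
    brightness_min_gain: float = 1.5  # criterion 3: peak >= beta * axonal median
    central_window_um: tuple[float, float] = (10.0, 20.0)

    def __post_init__(self):
        if not 0 < self.central_absence_max_ratio <= 1:
            raise ValidationError("central_absence_max_ratio must lie in (0, 1]")
        if self.brightness_min_gain < 1:
            raise ValidationError("brightness_min_gain must be >= 1")
        if not self.proximal_window_um > 0:
            raise ValidationError("proximal_window_um must be positive")


@dataclass
class ClusterCall:
    cell_id: str
    c1: bool
    c2: bool
    c3: bool
    region_means: dict = field(default_factory=dict)

    @property
    def n_met(self) -> int:
        return int(self.c1) + int(self.c2) + int(self.c3)

    @property
    def category(self) -> str:
        return {3: "+", 2: "~"}.get(self.n_met, "-")


def classify_cluster(
    presence: LineProfile,
    intensity: LineProfile,
    ais_start: AISStart,
    criteria: ClusterCriteria | None = None,
) -> ClusterCall:
    """Apply the three cluster criteria to one cell's aligned profiles.

    Both profiles must run along the same path (arclength 0 at the somatic
    end). A profile that does not reach the end of the central window cannot
    be scored and raises :class:`InvalidCellError`.
    """
    criteria = criteria or ClusterCriteria()
    if abs(presence.step_um - intensity.step_um) > 1e-9 or (
        presence.values.size != intensity.values.size
    ):
        raise ValidationError("presence and intensity profiles must share the same axis")
    start = ais_start.start_um
    needed = start + criteria.central_window_um[1]
    if presence.length_um < needed or intensity.length_um < needed:
        raise InvalidCellError(
            f"cell {presence.cell_id}: profile shorter than the central window"
        )
    s = presence.arclengths_um
    prox = (s >= start - criteria.proximal_window_um) & (s <= start + criteria.proximal_window_um)
    cen = (s >= start + criteria.central_window_um[0]) & (
        s <= start + criteria.central_window_um[1]
    )
    axonal = s >= start
    prox_presence = float(presence.values[prox].mean())
    cen_presence = float(presence.values[cen].mean())
    peak = float(intensity.values[prox].max())
    med = _axonal_brightness_reference(presence.values, intensity.values, axonal)
    c1 = prox_presence >= criteria.presence_min_fraction
    c2 = cen_presence <= criteria.central_absence_max_ratio * prox_presence
    c3 = peak >= criteria.brightness_min_gain * med
    return ClusterCall(
        presence.cell_id,
        c1,
        c2,
        c3,
        region_means={
            "proximal_presence": prox_presence,
            "central_presence": cen_presence,
            "proximal_peak_intensity": peak,
            "axonal_median_intensity": med,
        },
    )


def _axonal_brightness_reference(
    presence: np.ndarray, intensity: np.ndarray, axonal: np.ndarray
) -> float:
    """Typical axonal mitochondrion brightness: the median of per-mitochondrion
    peak intensities (maximum within each connected presence run).

    Criterion 3 compares mitochondria with mitochondria; the median over all
    mito-covered samples would be deflated by off-centre samples, and the
    plain profile median would measure background between the sparse puncta.
    Falls back to the axonal profile median when no mitochondrion is present.
    """
    on = (presence > 0) & axonal
    if not on.any():
        return float(np.median(intensity[axonal]))
    edges = np.flatnonzero(np.diff(np.concatenate([[0], on.astype(int), [0]])))
    run_maxima = [float(intensity[a:b].max()) for a, b in zip(edges[::2], edges[1::2])]
    return float(np.median(run_maxima))


def cluster_ratio(n_plus: int, n_tilde: int, n_minus: int) -> tuple[float, float]:
    """The cohort summary ratio and the positive fraction.

    ``printed_ratio = n_total / (n+ + 0.5 n~)`` (NaN when the denominator is
    zero) and ``positive_fraction = (n+ + 0.5 n~) / n_total``; their product
    is 1 whenever both are defined.
    """
    n_total = n_plus + n_tilde + n_minus
    if n_total <= 0:
        raise ValidationError("need at least one classified cell")
    weighted = n_plus + 0.5 * n_tilde
    printed = n_total / weighted if weighted > 0 else float("nan")
    return printed, weighted / n_total


def summarize_calls(calls: list[ClusterCall]) -> dict:
    counts = {"+": 0, "~": 0, "-": 0}
    for c in calls:
        counts[c.category] += 1
    printed, frac = cluster_ratio(counts["+"], counts["~"], counts["-"])
    return {
        "n_plus": counts["+"],
        "n_tilde": counts["~"],
        "n_minus": counts["-"],
        "printed_ratio": printed,
        "positive_fraction": frac,
    }


# ---------------------------------------------------------------------------
# axon calibre


def cross_section_area_um2(diameter_um):
    """Cross-sectional area extrapolated from the diameter: (x/2)^2 * 0.6 * pi."""
    d = np.asarray(diameter_um, dtype=float)
    out = (d / 2.0) ** 2 * 0.6 * np.pi
    return float(out) if np.isscalar(diameter_um) else out


def diameter_and_area_profile(
    stack: ImageStack,
    path: PathAnnotation,
    channel: str = "VOL",
    step_um: float = 1.0,
    max_radius_um: float = 3.0,
) -> pd.DataFrame:
    """Axon diameter every ``step_um`` from the volume channel.

    At each position the perpendicular intensity cut is interpolated and the
    diameter is its full width at half maximum; the cross-sectional area is
    extrapolated from the diameter. Positions whose cut leaves the image are
    skipped and flagged.
    """
    img = stack.channel(channel)
    px = stack.pixel_size_um
    pts, normals, arcs = resample_path(path.points_px, px, step_um)
    offs = np.linspace(-max_radius_um, max_radius_um, int(2 * max_radius_um / (0.25 * px)) + 1)
    coords = swath_coordinates(pts, normals, offs, px)
    h, w = stack.shape_yx
    rows = []
    for i, s in enumerate(arcs):
        c = coords[i]
        inside = (c[:, 0] >= 0) & (c[:, 0] <= w - 1) & (c[:, 1] >= 0) & (c[:, 1] <= h - 1)
        if not inside.all():
            rows.append({"position_um": s, "diameter_um": np.nan, "area_um2": np.nan, "ok": False})
            continue
        cut = sample_image(img, c)
        half = cut.max() / 2.0
        above = cut >= half
        if not above.any() or cut.max() <= 0:
            rows.append({"position_um": s, "diameter_um": 0.0, "area_um2": 0.0, "ok": True})
            continue
        centre = int(np.argmax(cut))
        lo = centre
        while lo > 0 and cut[lo - 1] >= half:
            lo -= 1
        hi = centre
        while hi < cut.size - 1 and cut[hi + 1] >= half:
            hi += 1
        doff = offs[1] - offs[0]
        # sub-sample linear interpolation of the two half-max crossings
        left = offs[lo]
        if lo > 0 and cut[lo] != cut[lo - 1]:
            left = offs[lo] - doff * (cut[lo] - half) / (cut[lo] - cut[lo - 1])
        right = offs[hi]
        if hi < cut.size - 1 and cut[hi] != cut[hi + 1]:
            right = offs[hi] + doff * (cut[hi] - half) / (cut[hi] - cut[hi + 1])
        diam = float(right - left)
        rows.append(
            {
                "position_um": s,
                "diameter_um": diam,
                "area_um2": cross_section_area_um2(diam),
                "ok": True,
            }
        )
    return pd.DataFrame(rows)


def mass_vs_volume_profile(
    mito: LineProfile, volume: LineProfile, ais_start: AISStart
) -> pd.DataFrame:
    """Mitochondrial-mass and volume curves on the AIS-aligned axis, each
    normalized so its first retained value equals 1."""
    if abs(mito.step_um - volume.step_um) > 1e-9 or mito.values.size != volume.values.size:
        raise ValidationError("mito and volume profiles must share the same axis")
    if mito.values[0] <= 0 or volume.values[0] <= 0:
        raise ValidationError("first profile value must be positive for normalization")
    axis = mito.arclengths_um - ais_start.start_um
    return pd.DataFrame(
        {
            "position_um": axis,
            "mito_norm": mito.values / mito.values[0],
            "volume_norm": volume.values / volume.values[0],
        }
    )


# ---------------------------------------------------------------------------
# end-to-end convenience


def classify_from_stack(
    stack: ImageStack,
    path: PathAnnotation,
    criteria: ClusterCriteria | None = None,
    seg_config=None,
    mito_channel: str = "MITO",
    ais_channel: str = "AIS",
    map2_channel: str = "MAP2",
) -> ClusterCall:
    """Full per-cell pipeline: detect the AIS start on the AIS channel,
    segment mitochondria, build presence/intensity profiles and classify.

    The diffuse somatic mitochondrial signal is removed from the mask (via the
    MAP2-derived soma region, when a MAP2 channel exists) so that the proximal
    window measures axonal mitochondria rather than perisomatic glow.
    """
    from .errors import NoSomaError
    from .profiles import binary_presence_profile, detect_ais_start, extract_profile
    from .segment import segment_mitochondria, somatodendritic_rois

    ais_profile = extract_profile(stack, ais_channel, path)
    start = detect_ais_start(ais_profile)
    mask = segment_mitochondria(stack, channel=mito_channel, config=seg_config)
    if map2_channel in stack.channel_names:
        try:
            for region in somatodendritic_rois(stack, channel=map2_channel):
                mask = mask & ~region.soma_mask
        except NoSomaError:
            pass
    presence = binary_presence_profile(stack, mask, path)
    intensity = extract_profile(stack, mito_channel, path)
    return classify_cluster(presence, intensity, start, criteria)
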