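# Methods

This note documents the measurement procedures, the synthetic-data model
behind the test suite, and the numerical choices that were genuinely open.

## Conventions

Pixel coordinates are 0-based with a pixel's centre at its integer
coordinate; points are (x, y). Only isotropic pixel grids are supported
(pixel pitch `pixel_size_um`); anisotropic input is rejected. Arclength 0 of
every neurite path is its first vertex, the somatic end, and all distances
are micrometres. Z-stacks are assumed collapsed (max projection) before
analysis; the package operates on 2D planes plus an optional time axis.

## AIS-start detection

The AIS marker profile is extracted along the annotated axon polyline by
bilinear interpolation, averaged across a perpendicular line width (default
3 px, the common plot-profile convention; default sampling step = pixel
pitch). The profile is smoothed with a **centred** boxcar of 1 µm (edge
windows shrink to the available support — the centred variant preserves
affine profiles in the interior, which makes the closed-form checks exact),
and the start is the smallest arclength whose smoothed value is ≥ 30 % of
the smoothed maximum.

Two consequences are worth knowing:

- The rule is invariant to multiplying the profile by any positive gain but
  **not** to adding a constant offset (the 30 %-of-max level shifts) — this
  is inherent to a percent-of-max rule and is covered by tests.
- On a linear onset ramp of width w the smoothed profile crosses 30 % of the
  plateau about `sqrt(0.6) − 0.5 ≈ 0.27` µm (for w = 1 µm) *after* the true
  onset; with 0.1 µm profile sampling the detector therefore reports a
  constant ≈ +0.3 µm offset on generated scenes. This bias is well inside
  the ±0.5 µm acceptance band and is deterministic, not random.

Degenerate inputs: an all-zero profile raises a "no AIS" error; a profile
whose maximum sits at arclength 0 returns start 0 with an `at_origin` flag.

## Presence profiles and replicate-weighted averaging

Binary presence along the axon is 1 wherever any foreground pixel of the
mitochondrial mask lies within the line width of the path sample. Per-cell
profiles are aligned to the AIS start on a shared grid (nearest-sample
alignment; profiles are binary so interpolation would be meaningless), then
averaged hierarchically: cell means within each biological replicate first,
then the unweighted mean (and SD) across replicates. Positions covered by
fewer than `min_cells` cells in total (default 3) are dropped entirely, as
profile lengths differ between cells and the extremes are unreliable.
Window means (proximal/central/distal) use 10 µm spans; the proximal window
is centred on the AIS start and the central/distal windows are shifted by a
fixed, configurable offset (default 15 µm, i.e. central = [+10, +20] µm).
The offset is a config knob because only the *equality* of the spacing is
fixed by the procedure, not its value.

## Mitochondria segmentation

The pixel-classifier step of the original workflow is replaced by
deterministic thresholding behind a pluggable interface
(`global_otsu` (default), `adaptive_local`, `fixed`); the downstream
statistics consume only the binary mask, so a trained classifier can be
slotted in without touching anything else. Global Otsu is scale-invariant
(handling expression-level differences between cells) and exactly invariant
to additive offsets; objects below `min_object_area_um2` (default 0.15 µm²)
are removed. In the full classification pipeline the diffuse somatic
mitochondrial signal is additionally excluded via the MAP2-derived soma
region, so the proximal window measures axonal mitochondria rather than
perisomatic glow — the role the pixel classifier played originally.

Somatodendritic ROIs come from the MAP2 channel thresholded with the
**triangle** method (robust for dominant-background fluorescence; Otsu tends
to cut the dimmer dendrites next to a bright soma). Soma candidates are the
thick parts of the mask (Euclidean distance-to-background ≥ 3 µm), grown
back by the same radius, and must pass area ≥ 80 µm² and eccentricity ≤ 0.9
gates (both configurable; the gates are conventions, not measurements).
Remaining MAP2-positive pixels form the dendritic mask.

## Somatic intensities and normalization

Background is measured per image: the mean inside an annotated background
ROI when one exists, otherwise the mean of the lowest decile of pixels
outside all cell masks. Note the decile fallback is biased low by roughly
1.3 SD of the noise; an annotated background ROI is preferred whenever
available. Corrected somatic intensity = soma mean − background; fold
change = corrected value / mean corrected value of control cells, making
the control mean exactly 1. The construction is exactly invariant to global
additive offsets (background subtraction) and to global multiplicative gain
(cancels in the control ratio).

The MAP2 polarity index divides the corrected somatic mean by the corrected
dendritic level; the dendritic level is the **median** over the dendritic
mask because the automatically derived mask unavoidably contains a few
axonal/edge pixels and the median is robust to them.

ROI time series (membrane-potential-style measurements) are
background-corrected per frame and normalized to frame 0 per ROI, so global
photobleaching affects all ROIs identically.

## Cluster classification

Criteria (defaults in parentheses, all configurable):

1. presence: mean presence in [start − 7.5, start + 7.5] µm ≥ 0.3;
2. central absence: central-window presence ≤ 0.5 × proximal presence
   (central window = the region-mean central window, [+10, +20] µm);
3. brightness: maximum proximal intensity ≥ 1.5 × the typical axonal
   mitochondrion brightness.

The criteria are qualitative in origin ("visible accumulation"); the
numeric defaults were chosen so that the generator's strong-cluster and
no-cluster conditions separate cleanly, and they are documented as tunable.
The brightness reference for criterion 3 is the **median of
per-mitochondrion peak intensities** (the maximum within each connected
presence run beyond the AIS start): the plain profile median would measure
background between the sparse puncta, and a median over all mito-covered
samples is systematically deflated by off-centre samples. With no
mitochondrion beyond the start the reference falls back to the axonal
profile median and criterion 3 effectively tests signal over background.

Categories: 3 criteria → "+", 2 → "~", ≤ 1 → "–". Cells whose profile does
not reach the end of the central window cannot be scored and are excluded.
The classifier is invariant to global multiplicative gain (all criteria are
ratios) and monotone in proximal punctum *amplitudes* (raising them can
never demote a call); monotonicity in presence is not guaranteed because
added proximal mitochondria legitimately shift the brightness reference.

The cohort ratio n_total/(n₊ + 0.5 n~) is reported exactly as defined (the
decimal-comma constant is read as 0.5), together with the positive fraction
(its reciprocal). The printed formula yields values ≥ 1 while published
cohort plots of "ratio of cells showing the cluster morphology" sit around
0.3–0.45 — the scale of the positive fraction; both numbers are therefore
always emitted and the discrepancy is flagged rather than resolved.

## Axon calibre and mass-vs-volume

Diameter is measured every 1 µm as the FWHM of the perpendicular volume
channel cut (linear sub-sample interpolation of the half-max crossings;
cuts that leave the image are skipped and flagged). Cross-section is
extrapolated as (d/2)²·0.6·π — the 0.6 factor models the non-circular
axonal cross-section. Mass-vs-volume curves divide the raw mitochondrial
and volume-marker profiles by their own first retained value (both curves
start at 1) on the AIS-aligned axis.

## Kymographs and trafficking events

Kymograph rows are maximum intensity across the line width per arclength
and frame. Event detection per channel: subtract the per-row temporal
median (removes every stationary structure, including the photoconverted
cluster band — which is therefore never an event), clip at 0, Otsu
threshold, 8-connected components, then an intensity-weighted centroid
track per component with a least-squares speed fit. Gates: track span ≥ 3
frames, |displacement| ≥ 2 µm, |speed| ≥ 0.1 µm/s, and the distance range
must overlap the cluster span ("went past the cluster"; a stricter
full-traversal mode is available). Direction follows the sign of the net
displacement; origin is "cluster" iff the event is in the red
(photoconverted) channel **and** its track starts inside the cluster span
(±1 µm tolerance). Without a red channel all events are labelled "other"
with a warning (non-photoconversion experiments). Crossing same-channel
tracks are not disambiguated — the scripted-movie tests use non-crossing
events, and this is a known limitation for dense real movies.

Per-cell fractions (cluster/other, antero/retrograde) are computed over
each cell's own events; cells without any event are excluded rather than
counted as zero, and cohort means average the per-cell fractions.

## Statistics

The statistics module only maps design names to standard procedures:
Welch's t; one-way ANOVA with Dunnett (scipy) or Tukey HSD; and for the
unequal-variance design, Welch's ANOVA (pingouin) with Games–Howell
contrasts against control — the standard unequal-variance post hoc, used
here in place of a Brown–Forsythe/Dunnett-T3 pairing. Shapiro–Wilk
normality is reported per group. Zero-variance degenerate groups are
decided by their means alone (identical groups → p = 1, different constant
groups → p = 0). The unit of analysis defaults to cell-level values
(matching the n's typically quoted alongside such tests); a flag switches
to replicate means, which matches the replicate-weighted profile
statistics. Replicate summaries weight replicates equally regardless of
cell count.

## Synthetic data model

Scenes are rendered at 0.2 µm/px (default 384 × 704): a disc soma, a
~80 µm axon and (default) three dendrites as bounded-curvature random-walk
polylines (draws that leave the canvas are redrawn deterministically before
the configuration is declared infeasible). Channels: MAP2 (soma +
dendrites, decaying over the proximal axon), AIS marker (zero before the
start, **linear 1 µm onset ramp** — matching the smoothed detection rule's
assumptions; the step case is kept as a unit-test fixture — then a plateau
over the AIS extent and exponential decay), TAU (somatic mean =
`tau_somatic_fold` × a fixed axonal reference; the treatment effect is
purely somatic), a volume channel with a linearly tapering width profile,
and mitochondria as Gaussian puncta (σ = 0.45 µm) whose rendered integral
equals amplitude × 2πσ² (conservation-checked to 2 %).

Mitochondrial statistics: baseline linear density 0.25 puncta/µm — chosen
so the noise-free binary presence fraction along an unremarkable axon
stretch is ≈ 0.33–0.37, the scale reported for distal-axon presence;
amplitude jitter is a clipped normal (SD 12 %). A cluster cell adds 6
puncta at 3× amplitude within ±7.5 µm of the AIS start and thins central
puncta to 20 % (`central_depletion_factor`). Noise = Poisson shot noise +
Gaussian read noise (SD 2) + constant background 20; identical seeds give
bitwise-identical pixels. Movies render static green puncta, the
photoconverted red cluster band and scripted moving puncta on a straighter
axon; optional global exponential photobleaching.

The random-script builder commits each event's origin (cluster with the
requested probability) and direction *before* rejection-sampling its
kinematics, so placement failures cannot bias the composition — this keeps
the binomial recovery oracles exact. Scripted events all overlap the
cluster span, are pairwise non-crossing within a channel, and stay within
the axon extent.

What the generator deliberately does **not** model: optics (no PSF,
hard-edged tubes), 3D structure, mitochondrial fission/fusion or pausing
particles, inhomogeneous illumination, and cell-to-cell expression
variability beyond amplitude jitter. Passing recovery tests therefore shows
the estimators are correct under the stated statistical structure, not that
segmentation or event detection is robust to every real-microscopy
artefact.

## Problem sizes

The test suite and acceptance script use desk-scale cohorts chosen to make
the binomial/recovery bounds meaningful: 100 noise-free scenes for AIS
recovery, 45 cells (3 replicates) for presence recovery, 50 + 50 cells for
classifier sensitivity/specificity, 40 cells/arm for fold-change recovery,
20 scripted movies plus 25 cells × 20 events for trafficking, and 1000
simulated runs for the type-I error check.
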