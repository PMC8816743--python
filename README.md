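# aismito

Quantification of mitochondrial clustering at the axon initial segment (AIS)
and of axodendritic TAU (mis)sorting from fluorescence microscopy.

## The problem

In cortical neurons a subset of cells carries a stationary cluster of
mitochondria in the proximal AIS — within about ±7.5 µm of the AIS start —
followed by a stretch of central AIS that is conspicuously poor in
mitochondria. This cluster sits exactly where the cell maintains its
axodendritic polarity, and impairing it (locally or globally) causes TAU to
accumulate in the soma, a hallmark of tauopathies. Quantifying these
phenomena from images requires a small set of recurring measurements:

- **AIS start detection** from an AIS-marker (ANKYRIN-G/TRIM46-like) line
  profile along the axon: the profile is smoothed with a 1 µm centred
  sliding mean and the start is the first arclength where the smoothed
  profile reaches 30 % of its maximum.
- **Mitochondrial presence profiles**: the mitochondrial channel is
  thresholded to a binary mask, sampled along the same line, aligned to the
  AIS start per cell and averaged with a *biological-replicate-weighted*
  mean (per-replicate cell means first, then the unweighted mean across
  replicates). Distribution differences are tested on 10 µm window means
  (proximal / central / distal, equally spaced).
- **Cluster classification** per cell on three criteria: (1) mitochondria
  present in the proximal AIS (±7.5 µm); (2) relative absence in the central
  AIS; (3) visibly brighter mitochondria proximally than elsewhere along the
  axon. 3 criteria met → cluster (+), 2 → (~), ≤ 1 → (–). The cohort summary

  ratio = n_total / (n₊ + 0.5·n~)

  is reported together with its reciprocal, the positive fraction
  (n₊ + 0.5·n~) / n_total.
- **Axon calibre**: diameter every 1 µm from a volume marker (FWHM of the
  perpendicular intensity cut) and the extrapolated cross-section
  A = (d/2)²·0.6·π.
- **Trafficking**: kymographs along the axon from two-channel
  (photoconversion) movies; events that pass the cluster are counted,
  classified as anterograde/retrograde and cluster/other origin, and
  expressed as fractions of each cell's total events.
- **Somatic intensities**: background-corrected somatic TAU (or MAP2, or
  TMRM time series) normalized to control cells, so the control mean is 1 by
  construction.

Because the primary microscopy data behind such studies are rarely
deposited, the package ships a synthetic-scene generator
(`aismito.synthetic`) that renders five-channel neurons (MAP2, AIS, MITO,
TAU, volume) and two-channel time-lapse movies with complete ground truth —
every estimator in the package can be validated against the generative
parameters, and all tests run without any download.

## Worked example

```python
from aismito import (classify_from_stack, cluster_ratio, detect_ais_start,
                     extract_profile, generate_scene)
from aismito.synthetic import SceneConfig

cfg = SceneConfig(seed=42, cluster_present=True)
stack, truth, ann = generate_scene(cfg)
path = ann.path("cell0", "axon")

profile = extract_profile(stack, "AIS", path, step_um=0.1)
start = detect_ais_start(profile)
print(f"AIS start: detected {start.start_um:.2f} um (truth {truth.ais_start_um:.2f} um)")

call = classify_from_stack(stack, path)
print(f"cluster call: {call.category}  (criteria met: {call.n_met})")
printed, frac = cluster_ratio(3, 2, 5)
print(f"printed ratio for (3, 2, 5): {printed}  positive fraction: {frac}")
```

prints

```
AIS start: detected 5.30 um (truth 5.00 um)
cluster call: +  (criteria met: 3)
printed ratio for (3, 2, 5): 2.5  positive fraction: 0.4
```

The detected start sits 0.3 µm distal of the truth — the expected offset of
the 30 %-of-max rule on a 1 µm onset ramp (see `docs/methods.md`). The cell
was generated with a cluster and is called (+): mitochondria cover 66 % of
the proximal window, 16 % of the central window, and the proximal peak is
~3.9× the typical axonal mitochondrion brightness.

A command-line interface mirrors the main steps:

```bash
aismito simulate --n-cells 20 --cluster-fraction 0.4 --seed 1 --out cohort/
aismito detect-ais --cohort cohort/
aismito classify --cohort cohort/ --out calls.csv
aismito report --measurements folds.csv --metric fold --design one_way_anova_dunnett
```

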