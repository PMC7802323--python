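# cellmech

Biophysical image-analysis toolkit for quantifying how perturbations
(e.g. nanoparticle exposure) change the mechanics of adherent cells.
It implements four measurement chains, each validated against
synthetic scenes with known ground truth:

* **Micropillar traction-force microscopy** — sub-pixel detection of
  elastomeric pillar tops, robust reconstruction of the rest lattice,
  frame-to-frame deflection tracking, stage-drift correction from
  cell-free reference pillars, and force conversion via the
  Euler–Bernoulli cantilever stiffness
  `k = (3/64) π E D⁴ / L³` (defaults: D = 0.9 µm, L = 1 µm,
  E = 2 MPa, pitch 1.8 µm → k = 193.2 nN/µm), with per-cell
  aggregation of `F = k·d`.
* **Laurdan generalized polarization (GP)** — per-pixel
  `GP = (I₄₂₀ − I₄₇₃)/(I₄₂₀ + I₄₇₃)` membrane-fluidity maps, binned
  frequency distributions with single-Gaussian fits,
  condition-difference curves, pooled mean GP, and overlap of high-GP
  (rigid) regions with a nanoparticle channel.
* **Morphometry and motility** — equivalent-ellipse aspect ratio of
  cell masks, travel distance / net displacement / mean velocity of
  5-min-sampled tracks, and one-way ANOVA with Bonferroni-adjusted
  pairwise comparisons.
* **Omics fold-change filters** — symmetric 3-fold gene and 20%
  metabolite cutoffs producing a network-node table for downstream
  pathway tools.

The `cellmech.simgen` module is a first-class part of the package: it
renders pillar-array movies (PSF-blurred disks, shot/read noise,
cumulative drift, planted deflections), two-channel laurdan scenes
whose GP field is exactly invertible at zero noise, persistent-random-
walk cell tracks with known speeds, and omics tables with planted fold
changes — each with a truth table, so every estimator is tested by
parameter recovery.

## Worked example

Recover planted traction forces from a simulated 20-frame pillar movie
(1.8 µm pitch, 10 pillars deflected by 0.1–0.4 µm under a central
cell, 0.05 µm/frame stage drift, 500-count peaks):

```python
import numpy as np
from cellmech import simgen, tfm

mask = simgen.disk_mask((192, 192), (96, 96), 40)          # cell footprint
spec = simgen.PillarSceneSpec(
    image_shape=(192, 192), pixel_size=0.2, n_frames=20,
    drift_per_frame=(0.05, 0.0), photon_level=500.0,
    read_noise_sd=2.0, cell_mask=mask, seed=20260929,
)
spec = simgen.add_random_deflections(spec, 10, (0.1, 0.4))
scene = simgen.simulate_pillar_sequence(spec)

geom = tfm.PillarGeometry()                                # k = 193.2 nN/µm
field, summary = tfm.analyze_pillar_stack(scene.stack, geom, 0.2, mask)
print(f"mean |d| = {summary['mean_displacement_um']:.3f} um, "
      f"mean |F| = {summary['mean_force_nN']:.1f} nN, "
      f"total |F| = {summary['total_force_nN']:.0f} nN")
```

prints

```
mean |d| = 0.051 um, mean |F| = 9.8 nN, total |F| = 606 nN
```

i.e. the 62 pillars under the cell are deflected by 51 nm on average
(most are undeflected; the 10 planted pillars dominate), the mean
per-pillar force is 9.8 nN, and the summed magnitude of all under-cell
pillar forces is 606 nN. Matching against the scene's truth table, the
median per-pillar force recovery error is 1.9% and the residual
displacement of the cell-free reference pillars after drift correction
is 7.7 nm, against 50 nm/frame of planted drift
(`analysis/02_tfm_forces.py` prints exactly this narrative).

The numbered scripts under `analysis/` walk the full chain on demo
data — `01` simulates all scenes, `02` recovers traction forces, `03`
contrasts GP distributions of fluid vs rigidified membranes, `04`
compares motility and shape between conditions, `05` applies the
fold-change filters — writing their tables under `results/`.

A `cellmech` CLI wraps the same library for shell use
(`cellmech run --config config.json`, plus `gp-analyze`,
`tfm-analyze`, `morpho`, `track`, `omics-filter` subcommands); every
run writes a manifest echoing the exact configuration and seed, and
fixed seeds reproduce all outputs byte for byte.

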