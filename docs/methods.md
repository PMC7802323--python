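# Methods

`cellmech` implements the biophysical analysis chain used to quantify
nanoparticle effects on adherent cells: membrane fluidity from laurdan
ratiometric imaging, traction forces from elastomeric micropillar
deflections, cell shape and motility metrics, and fold-change filters
that prepare gene/metabolite tables for network analysis. Every
estimator is paired with a forward simulator with exact ground truth,
so the whole chain is validated by parameter recovery rather than by
eyeballing images.

## Micropillar traction-force microscopy

**Physical model.** Each PDMS post is a cantilevered beam; for small
tip deflections the restoring force is linear, `F = k d`, with the
Euler–Bernoulli stiffness for a circular cross-section

```
k = 3 E I / L^3,   I = pi D^4 / 64   =>   k = (3/64) pi E D^4 / L^3.
```

Defaults are `D = 0.9 um`, `L = 1 um`, `E = 2 MPa`, pitch `1.8 um`,
giving `k = 193.2 nN/um`. An instrument-calibrated override can be
supplied instead; when the override disagrees with the beam-theory
value by more than 5% the stiffness report carries an explicit
discrepancy note (a factor of 8 corresponds to an effective length of
`2L`, since `k ∝ 1/L^3`), and every output states which stiffness was
used. Small-deflection linearity is assumed throughout; substrate
warping and pillar-top/base parallax are not modelled.

**Detection.** Pillar tops are bright PSF-blurred disks. Candidates
come from a local-maximum filter at 0.6-pitch spacing; each is refined
by an iterated centre of mass in a circular window of radius
0.4 pitch, recentred until convergence (tolerance 1e-4 px). A pedestal
of 30% of the local peak amplitude (above the 10th-percentile
background) is clipped off the weights before the centroid: for a
radially symmetric spot this leaves the estimate unbiased, while it
suppresses the asymmetric tail overlap from neighbouring pillars on a
dense lattice, which otherwise biases displaced pillars by several
hundredths of a pixel. Measured accuracy on simulated arrays
(pitch 9 px, PSF sigma 1.5 px): < 0.01 px worst case without noise,
~0.035 px RMS at 500-count peaks with shot and read noise.

**Lattice reconstruction.** The undeformed (rest) grid is fitted
directly to frame-0 detections: orientation is seeded from
nearest-neighbour direction statistics (circular mean with 4-fold or
6-fold symmetry for square/hexagonal packing), then the origin and a
full 2x2 basis are refined by iterated least squares with residual
trimming (inliers within `max(3 * median residual, 0.02 pitch)`), so a
minority of cell-deflected pillars cannot bias the rest positions of
the majority. Fits with RMS residual above pitch/4 are rejected as a
wrong lattice model, as are duplicate node assignments. With 10% of
pillars deflected by up to a quarter pitch the recovered rest
positions stay within 0.03 px of truth.

**Tracking and drift.** Pillars are followed frame to frame by
matching each one to the detection nearest its previous position,
gated at pitch/2 *on the increment*. Gating the increment rather than
the absolute offset from the rest node matters because slow stage
drift accumulates: at 0.05 um/frame a 20-frame movie drifts a full
1 um, beyond the 0.9 um half-pitch gate that a nearest-node assignment
would use. Raw displacement is still detection minus rest node;
missing pillars are flagged, never interpolated. Pillars whose rest
position lies farther than a margin (default 2 um) from the cell mask
are reference pillars; the per-frame mean of their raw displacements
estimates stage drift and is subtracted from every pillar, making the
mean corrected reference displacement exactly zero by construction.

**Aggregation.** Per pillar, displacement and force magnitudes are
averaged over tracked frames; the per-cell summary reports the mean
|d|, mean |F| and total |F| over under-cell pillars, where *total* is
the sum of per-pillar force magnitudes. The net vector sum is also
reported, but it nearly cancels for a contractile cell and is not the
headline number. Both the per-pillar table and the per-cell summary
are emitted so either pooling convention can be applied downstream.

## Laurdan generalized polarization

Laurdan's emission spectrum blue-shifts in ordered (rigid) lipid
phases. With registered emission channels at 420 and 473 nm the
per-pixel index

```
GP = (I420 - I473) / (I420 + I473)    in [-1, 1]
```

is higher for more ordered, less fluid membrane. The simulator
constructs channels as `I420 = T (1 + GP)/2`, `I473 = T (1 - GP)/2`
before noise, which makes the estimator exactly invertible at zero
noise — the analytic oracle used by the tests. No spectral (G-factor)
calibration is applied; the index is the raw two-channel ratio.

Background pixels are excluded where `I420 + I473` falls below a
threshold; the default is Otsu's threshold of the sum image, and both
a scalar threshold and an explicit mask can override it. Frequency
distributions use 100 bins over [-1, 1] (width 0.02, configurable) and
normalize to unit sum; a single Gaussian is fitted by least squares
(`curve_fit`, moment-based initial values, sd bounded positive), with
non-convergence — including histograms with fewer than five occupied
bins — flagged rather than raised. Difference curves subtract one
normalized distribution from the other per bin and therefore sum to
zero; the orientation (which condition is the minuend) is recorded in
the result, with control-minus-treated the conventional default.
Summary GP is the arithmetic mean over masked-in pixels (pooled
pixels; per-cell means can be formed by passing per-cell masks).

High-GP/nanoparticle colocalization is quantified as the fraction of
pixels above a GP threshold that also exceed a nanoparticle-channel
threshold. This is one reasonable operationalization of a qualitative
claim, not a standard of the field; with no high-GP pixels it is
undefined and reported as NaN with a flag.

## Morphometry and motility

Cell shape uses the equivalent ellipse — the ellipse with the same
second-order image moments as the mask (via `regionprops`); the aspect
ratio is major/minor axis and is invariant to rotation, translation
and scale up to discretization. Masks must be single connected
components of at least 20 px; degenerate line-like masks are rejected.

Tracks sampled at a fixed interval (default 5 min over 6 h) yield
travel distance (sum of step lengths), net displacement, and mean
velocity defined as path length over elapsed time; per-step
instantaneous speeds are also emitted. Gaps of up to 2 missing samples
are bridged linearly; longer gaps split the track, since at 5-min
sampling short dropouts are benign but long ones are not
interpolatable. Group comparisons use one-way ANOVA with pairwise t
tests and Bonferroni adjustment (`p_adj = min(1, m p)`), significant
at `p < 0.05`.

## Omics fold-change filters

Gene tables are filtered at a symmetric linear 3-fold cutoff:
`max(r, 1/r) > 3` with `r = treated/control`, so down-regulation is
treated like up-regulation (a log2 cutoff would be equivalent; linear
is the convention adopted and the cutoff is configurable). Metabolites
pass at `|treated - control| / control > 0.20`. Both filters are
strict inequalities, monotone in their cutoff, and skip non-positive
levels with a warning count instead of dropping rows silently. Flagged
features are exported as a combined node table (id, class, direction,
magnitude) for external network tools; tables are assumed
pre-normalized upstream.

## Synthetic scenes: what they emulate, and what they do not

The pillar simulator renders each post as a uniform disk convolved
with an isotropic Gaussian PSF (radial profile computed by quadrature
of the exact Bessel-kernel convolution integral), on a uniform
background, with Poisson shot noise and Gaussian read noise, global
cumulative stage drift, and planted per-pillar deflections that are
rejected if they reach half the pitch (tracker identifiability) or
target pillars outside the cell mask. Defaults follow the targeted
experiment: square 1.8 um lattice, 0.9 um posts, bright spots on a
dark background, 500-count peaks. The laurdan simulator applies the
exact channel-splitting model above with per-channel noise; the track
simulator is a persistent random walk with per-cell speeds (normal,
truncated at zero) and constant step length, so the true mean speed
equals the drawn speed exactly; the omics simulator plants known fold
changes under multiplicative log-normal noise.

Not emulated: fluorophore photophysics (bleaching, blinking), 3-D
pillar bending profiles, photorealistic cell texture, cell
segmentation (masks are inputs), microscope aberrations beyond the
Gaussian PSF, and biological variability in force generation. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated imaging model, not robustness to every real-world
artefact.

Every scene draws all randomness from a single generator seeded from
its spec; fixed seeds give byte-identical outputs, and the pipeline
derives per-stage child seeds from one run seed.

## Problem sizes and tolerances used in validation

End-to-end traction recovery runs five 20-frame 192x192 movies
(~320 pillars each, 10 deflected at 0.1–0.4 um, 0.05 um/frame drift,
500-count peaks) and requires median relative force error below 5%
and mean reference residual below 0.02 um; measured values are ~1.5%
and ~0.008 um. Gaussian-fit recovery uses 1e5-pixel GP maps with a
0.01 tolerance on mean and sd. These sizes keep the full suite fast
while leaving the error margins far from their bounds.

## Known limitations

* The centroid localizer assumes approximately radially symmetric
  spots; strongly astigmatic optics would need a PSF-model fit.
* Greedy nearest-detection matching can in principle double-assign a
  detection when a neighbour goes missing; with deflections below half
  the pitch this does not occur, and missing pillars are flagged.
* The drift estimate is a per-frame translation; rotational or
  non-rigid stage drift is not modelled.
* The colocalization fraction depends on both thresholds; it is a
  descriptive overlap measure, not an inferential statistic.
* ANOVA/Bonferroni assumes independent samples and roughly equal
  variances; it mirrors the conventional workflow rather than a
  modern mixed-model treatment.
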