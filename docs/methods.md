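# Methods

## Problem and scope

`vesseltort` quantifies retinal blood-vessel tortuosity from binary
segmentation maps (as produced by automated fundus segmentation tools such
as AutoMorph) and evaluates how reliably each tortuosity metric reproduces
itself when the same eye is imaged twice within minutes. The package
contains four layers: centerline geometry, a panel of seven tortuosity
metrics, a test–retest reliability protocol, and a synthetic vasculature
generator that stands in for clinical images, which are typically not
shareable.

## Centerline geometry

A segmentation map is thinned to a one-pixel-wide skeleton (Zhang–Suen-type
morphological thinning via scikit-image). Skeleton pixels with three or
more skeleton neighbours are junctions; removing them decomposes the tree
into junction-free paths, each traversed end-to-end starting from the
endpoint with the smallest (row, column) coordinate. Paths shorter than
`min_length_px` (default 20 px) are discarded; artery/vein class is the
majority vote of an optional label raster along the path. All metrics are
computed per junction-free branch, in pixel units — none of the metric
definitions uses a physical length scale.

Each branch is resampled to uniform arc-length spacing (`spacing_px`,
default 1 px) and smoothed with a Gaussian of standard deviation
`sigma_px` (default 2 samples). Smoothing pads the ends by point
reflection through the endpoints, which keeps straight lines exactly
straight and endpoint positions stable to first order. The defaults were
chosen so that a straight rasterized vessel yields curvature ≈ 0 despite
pixel aliasing. First and second derivatives are central finite
differences with respect to arc length (one-sided at the endpoints);
signed curvature is κ = (x′y″ − x″y′)/(x′² + y′²)^{3/2}.

Inflection points are sign changes of κ with hysteresis: a breakpoint is
placed only between runs where |κ| exceeds `noise_threshold`
(default 10⁻³ px⁻¹) on both sides, at the sample of minimal |κ| in the
gap. The threshold is dimensional (1/length); analyses that rescale
coordinates should rescale it accordingly.

## The tortuosity panel

For a branch C with pieces C₁…Cₙ between consecutive inflection points
(arc lengths lᵢ, chords chordᵢ):

- **arc_over_chord** — the branch is cut into consecutive windows of equal
  arc length close to `window_px` (default 50 px; a final remainder
  shorter than half a window is absorbed into the window count). Value:
  arc-length-weighted mean of per-window arc/chord ratios. Equal-length
  windows make the partition exactly symmetric under orientation reversal.
- **distance_tortuosity** — same ratio but over the inflection pieces
  (dynamic endpoints); weighted by piece arc length.
- **angle_tortuosity** — per piece, the angular deviation
  ΔΘ = π − arccos(a·b/|a||b|) with a and b pointing from the piece's
  arc-length midpoint (interpolated on the curve) to its two endpoints;
  value is Σ lᵢΔΘᵢ / Σ lᵢ. The vectors are coordinate-free differences, so
  the quantity is translation invariant, and the interpolated midpoint
  makes it exactly reversal-symmetric. An alternative `denominator="n"`
  divides by the piece count instead of the total length.
- **tortuosity_density** — ((n−1)/n) · (Σ chordᵢ)⁻¹ · Σ (lᵢ/chordᵢ − 1).
  Zero for a branch without inflections. Because of the normalization by
  total chord length this metric carries 1/length units and scales as
  1/s under magnification by s — a genuine density, unlike the
  dimensionless ratio metrics.
- **squared_curvature** — trapezoidal ∫ κ² ds. The squared integrand
  amplifies pronounced bends; `power=1` integrates |κ| (total absolute
  turning) instead.
- **inverse_radius** — mean |κ|, i.e. the mean reciprocal of the
  osculating-circle radius in the image plane.
- **vci** — "VCI-open", described below.

Every metric also returns per-sample contributions used by the heatmap
renderer (vessel pixels coloured by the value at the nearest centerline
sample, min–max normalized per image, lighter = more tortuous).

Image-level aggregation is the arc-length-weighted mean of branch values,
reported for arteries, veins, and all vessels.

## VCI-open: reconstruction of the vascular curvature index

The original vascular curvature index is proprietary; only its physical
motivation is public — it measures the change of angular momentum
(L = Iω, with dL/dt = m·v·r′(t) for a point mass on a curved path) and was
designed to resist segmentation inaccuracies. VCI-open operationalizes
that description directly:

1. the branch coordinates are smoothed at the metric's own internal scale
   (`smoothing_sigma_samples`, default 4 samples);
2. the curve is treated as the trajectory of a unit-mass point at unit
   speed (m = v = 1, unit-tangent velocity);
3. for each interior sample i, over the window [i−w, i+w] (default w = 5),
   the planar angular momentum L = r × v is computed about the midpoint of
   the window's chord, and the sample's contribution is the window mean of
   |dL/ds| by finite differences;
4. the value is the mean contribution over interior samples.

A straight branch gives exactly 0 (r ∥ v throughout). The free parameters
of the reconstruction — the internal smoothing scale and window width —
were set by measuring retest stability on the synthetic calibration cohort,
mirroring the stated design intent of the original metric; the windowed
mean of |dL/ds| with a local reference point was retained over a
windowed *net* change of L, which cancels too much signal on
constant-curvature stretches. VCI-open is a documented stand-in: numeric
agreement with the proprietary implementation is not claimed.

## Reliability protocol

Given a long-format paired table (subject, eye, vessel class, metric,
test value, retest value):

- **Retest correlations** — Pearson and Spearman (average ranks on ties)
  between sessions, per metric and class. Eyes are kept as separate
  observations.
- **Stability t-tests** — for each metric, the pooled test+retest values
  are Box-Cox transformed (λ maximizing the profile log-likelihood on
  [−5, 5] by bounded scalar optimization, fitted per metric) and
  standardized; the per-(subject, eye) absolute difference of the two
  sessions' z-scores is the metric's instability score. For every ordered
  metric pair, a paired one-sided t-test (df = n−1, p = P(T ≤ t)) asks
  whether the first metric's instability scores are smaller. Z-scoring at
  the *value* level is essential: standardizing each metric's transformed
  absolute differences directly would force every paired mean difference
  to zero and make the test vacuous. Zero values before the Box-Cox are
  shifted up by half the smallest positive value (the transform requires
  positive inputs); exact ties across all pairs report t = 0, p = 0.5.
  Raw p-values are reported; Holm adjustment is available but off by
  default.
- **Distribution diagnostics** — Fisher-Pearson skewness
  g₁ = m₃/m₂^{3/2} (population form; adjusted form behind a flag).
- **Cross-metric correlations** — Pearson/Spearman matrices across the
  seven metrics on test-session values.

Operating characteristics, measured by simulation at n = 44 subjects with
lognormal between-subject levels and multiplicative measurement noise: a
metric with 10× the retest noise of a comparator is detected (p < 0.05) in
essentially 100% of 200 runs; under equal noise the rejection rate is
≈ 4–6%, i.e. the test holds its nominal level.

## Synthetic cohort and noise model

`CohortSpec` emulates a repeated-acquisition design: 44 subjects, both
eyes, two acquisitions. Each eye's anatomy is a set of sinusoidal vessels
in horizontal bands plus one vessel crossing them vertically — crossings
create skeleton junctions, and the sensitivity of junction decomposition
to noise is precisely what destabilizes endpoint-dependent metrics in real
segmentations. A per-subject lognormal multiplier (σ = 0.4) on vessel
amplitudes provides between-subject spread; vessels are rasterized at
3 px width into 168×220 maps with artery/vein labels.

Between-session variability has four seeded components, applied
independently per acquisition:

| component | default | models |
|---|---|---|
| sub-pixel field shift | σ = 0.5 px | head/camera repositioning |
| elastic deformation | rms 4 px, corr. length 12 px | low-frequency differences in the segmented vessel path |
| boundary pixel flips | p = 0.05 | pixel-scale segmentation/thresholding noise |
| drop-out gaps | Poisson(3)/image, radius 2–4 px | local segmentation failures at crossings/low contrast |

The defaults were calibrated once so that the established metrics land in
the 0.45–0.85 retest-Pearson range reported for fundus-photography
tortuosity; with them, the calibrated cohort yields median retest Pearson
(vessels, 3 seeds) of ≈ 0.69 (arc/chord), 0.70 (distance), 0.71 (angle),
0.56 (density), 0.38 (inverse radius), 0.34 (squared curvature) and 0.75
(VCI-open). The raster noise model is relatively harsher on bare
curvature statistics than real re-acquisition variability appears to be,
which is why the two curvature-energy metrics fall below that range here.

What the generator does *not* emulate: realistic branching topology and
vessel calibre hierarchy, optic disc and field-of-view geometry,
illumination or contrast variation, pathology, and genuinely re-run
segmentation networks. Passing the simulation therefore validates the
pipeline's mechanics and the metrics' comparative noise response under a
controlled noise family — not clinical-grade reliability figures.

One RNG stream is derived from the master seed per (subject, eye, session),
so enlarging a cohort never changes earlier subjects' data, and every
generator is bit-reproducible given (spec, seed).

## Numerical choices and degenerate inputs

- Windows and pieces with chords below 10⁻⁹ px raise a degenerate-chord
  error (e.g. a closed loop as a single window).
- Zero-speed samples (coincident points) are rejected; curve construction
  can deduplicate consecutive raster duplicates.
- Curves need ≥ 5 samples for derivatives and ≥ 2w+1 samples for VCI-open.
- Angle pieces with a zero-length arm are skipped with a warning; if all
  pieces are degenerate the metric errors out.
- Problem sizes in tests and in `scripts/acceptance.py` (168×220 rasters,
  4 vessels/eye, 3 cohort seeds, 200 t-test simulations) are the package's
  default desk-scale study; all are parameters that scale up directly.

## Known limitations

- VCI-open is a reconstruction from a physics sketch; its absolute values
  are not comparable to the proprietary index.
- Metrics are 2-D: vessels are treated as planar curves, appropriate for
  fundus photography but not for modalities that track vessels in depth.
- Branch-level measurement ignores anatomical vessel continuity across
  junctions; an anatomical-vessel mode would require junction matching,
  which is out of scope.
- The inflection threshold and window length are dimensional; analyses on
  images with very different resolutions should rescale them.
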