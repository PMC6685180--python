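# Methods

This note documents the models, parameters, and numerical choices behind
`zftrunk`, what the synthetic phantoms do and do not emulate, and the known
limitations of each measurement.

## NMJ quantification pipeline

The pipeline measures distributed (fast-twitch) innervation from
two-channel maximum projections.  Stages, in order, with their defaults:

1. **Maximum projection** per channel (pixelwise max over z-planes).
2. **CLAHE** (contrast-limited adaptive histogram equalization),
   `clahe_clip = 0.01` of the per-tile histogram.  `clahe_tile = None`
   uses an 8×8 tile *grid* (tile side = image side / 8), the default
   parameterization of the adaptive-equalization operator this stage
   models; an explicit integer sets the tile side in pixels.  Degenerate
   (constant) planes pass through unchanged; a tile larger than the image
   falls back to global equalization with a warning.
3. **Gaussian denoise**, `gaussian_sigma = 1` px ("1-pixel radius"),
   reflective boundaries, output in float so sub-integer structure
   survives; σ = 0 is the identity.
4. **Fixed threshold**, `intensity_threshold = 30` on the 8-bit scale,
   *inclusive* (a pixel exactly at 30 is foreground).  The inclusivity
   choice is immaterial in practice because group trends are stable over
   thresholds ≈ 10–58 (see threshold robustness below), but it is fixed
   and documented.
5. **OR-fusion** of the two channel masks.  Pre/post-synaptic apposition
   is deliberately not scored; the fused mask represents "any synaptic
   signal".
6. **Territory restriction**: fused ∧ fish ∧ ¬myoseptal-innervation,
   keeping distributed innervation only.
7. **Skeletonize / clean / despur**: topology-preserving thinning
   (Zhang–Suen); "clean" removes isolated single pixels; "despur" removes
   all current endpoints, repeated `spur_iterations = 1` times, then
   re-cleans stubs fully consumed by despurring.  Components smaller than
   `min_object_pixels` (default 0 = off) are dropped before thinning.
8. **Branchpoints**: skeleton pixels with ≥ 3 skeleton neighbors
   (8-connectivity).  Thinning leaves adjacent candidates at one junction,
   so 8-connected candidate clusters collapse to a single branchpoint at
   the cluster pixel nearest the centroid (ties broken in raster order).
9. **Per-half-myotome metrics**: skeleton length = pixel count carrying
   the half-myotome label (`length_metric = "pixels"`); a link-weighted
   length (1 per 4-link, √2 per diagonal link) is available as
   `"weighted"`.  Branchpoints belong to the segment containing their
   representative pixel.  Branchpoints per 100 skeleton px are emitted as
   a normalized extra column, since "degree of branching" has no unique
   algebraic definition.

Half-myotomes (a myotome's dorsal or ventral half, split at the
horizontal myoseptum) are the sampling unit, enumerated
anterior→posterior with dorsal before ventral.  An aggregation to whole
myotomes is a one-line `groupby` on the tidy output table and is left to
the caller.

**Bit depth.** The fixed threshold of 30 only makes sense on a 0–255
scale, so all ingestion rescales to 8-bit: 16-bit stacks are linearly
min–max rescaled using the global stack range (a constant stack maps to
zeros).  Intensities are comparable only within an acquisition batch;
the intensity-normalization step (below) enforces this.

## Synthetic trunk phantoms

The generator produces the study conditions under which the pipeline is
validated.  Geometry: `n_myotome_pairs = 10` chevron myotomes in a
168×560 px raster, full apex angle `mtj_angle = 90°`, horizontal
myoseptum as a ±2 px row band, myoseptal-innervation stripes as ±2 px
column bands along each chevron boundary, half-myotome label polygons
inset 3 px off the stripes.  The per-half-myotome baseline length is the
chevron arm span (≈ 101 px at the default geometry).

**Innervation chains.** Each half-myotome receives polylines of Gaussian
puncta (σ = 1.8 px, spacing 5 px, peak amplitude 160) whose summed length
is `chain_length_factor × arm span`, discretized to a whole number of
spacings — the recorded ground truth is therefore exact, not estimated.
Chains run anterior→posterior (the fiber direction) across the myotome
with only their start jittered, and chain rows keep a minimum separation
of 6 puncta-sigmas, a fiber-diameter-scale gap: distributed innervation
runs along distinct fast fibers, and non-overlapping chains are also what
makes per-segment skeleton length a faithful readout (a naive random
layout fragments into short overlapping runs whose merged bands
under-count the densest groups).  Each punctum spawns a 45° side chain
with probability 0.15 (geometric length, p = 0.5), contributing exactly
one ground-truth branchpoint.  Both channels share punctum positions
(pre/post-synaptic colocalization) and differ only by per-channel
amplitude and independent noise.

**Group presets** fix `chain_length_factor` at the published relative
skeleton lengths: control 1.0, fkrp-like 0.514, dag1-like 0.839,
NAD+-fkrp-like 0.619, NAD+-dag1-like 0.850.  Absolute pixel sizes are
uncalibrated (no µm metadata exists for the original acquisitions), so
presets are meaningful only as ratios.

**Noise model.** Additive Gaussian, `background_level = 2`,
`noise_sigma = 1` on the 8-bit scale, clipped to [0, 255]; optional
Poisson shot noise is off by default.  The near-black background is a
deliberate calibration to the data family the pipeline was designed for:
confocal projections acquired with the detector offset at the dark level.
It matters because CLAHE stretches whatever a tile contains — with
sigma ≳ 3 the equalized background of *sparse* images crosses 10, which
floods the lowest threshold of the 10–58 robustness band and does so
group-dependently (sparser morphant images flood more).  The stated
threshold-robustness of group trends is a property of the image family,
and the generator reproduces it; this was verified over multiple
independent seed sets, not a single configuration.

**What the phantoms do not emulate:** optical PSF beyond Gaussian spots,
z-structure (projections are synthesized directly), photobleaching,
autofluorescent muscle texture in the synaptic channels, slow-twitch
myoseptal innervation beyond a mask stripe, and biological variability in
myotome geometry.  Passing tests therefore demonstrate that the
*measurement chain* recovers known innervation differences under
realistic noise — not that it handles every artifact of real micrographs.

**Measurement fidelity on phantoms.** Skeleton length recovers truth with
slope ≈ 0.94 and r ≈ 0.95 across innervation densities; per-chain end
effects (threshold-contour caps minus thinning/despur shrink) roughly
cancel.  Branchpoint counts recover ≈ half of the laid-down branches:
one-step side chains lie mostly inside the main chain's thresholded band
and are invisible to thinning.  This is a genuine property of
skeleton-based branch counting at this spot size, shared by the original
measurement; group comparisons remain valid because the loss is
proportional across groups.

## MTJ angles, vessels, intensity, degeneration, tallies

- **MTJ angle**: interior angle at the apex from the two arm vectors
  (full chevron angle; the annotation stores the apex as the middle
  point).  Exact on annotations; invariant under similarity transforms
  and arm swap.  Degenerate (zero-length) arms are rejected.
- **Vessel length**: summed Euclidean length of the traced polyline;
  optional normalization by a user-supplied embryo width (the
  normalization denominator is a measured two-point width, not inferred).
- **Percent mean intensity**: `100 × ROI mean gray / mean of control ROI
  means`, always within an acquisition batch; the control group averages
  100% by construction.  Empty control groups or zero control means are
  errors, not NaNs.
- **Degeneration**: percent of myotomes flagged per embryo; flags are
  manual annotations (visual scoring), not automated detection.
- **Categorical tallies** accept only scores taken on blinded names —
  the scorer must not know the group — and unblind via a separate
  name→group mapping only at tally time.

**Blinding** assigns `blinded_<k><ext>` names from a seeded random
permutation; the key is written separately from the blinded data and the
analysis functions never read it.

## Anisotropy

The fiber-organization statistic is an orientation order parameter over
wavelet modulus maxima: Gaussian-derivative gradients at scales
{2, 4, 8} px, non-maximum suppression along the bilinearly interpolated
gradient direction, a relative modulus floor of 0.1 × the per-scale
maximum inside the ROI, orientations pooled across scales with equal
weight and doubled before averaging (standard for axial data).  The
factor is bounded in [0, 1], ≈ 1 for oriented texture and
≈ n<sup>−1/2</sup> for isotropy, and is reported as *missing* (not 0)
when fewer than 10 maxima survive the floor — a constant plane has no
orientation, which is different from an isotropic one.  The full
multifractal WTMM formalism (partition functions, maxima chaining across
scales) is intentionally not implemented; this statistic matches the
qualitative use of the published anisotropy factor (ordering of groups),
not its absolute scale.

Defaults: 36 angle bins for the diagnostic histogram; scale choice spans
the fiber-texture periods of interest (a grating with period ≲ 2× the
largest scale is strongly attenuated at that scale, which is why the
bundled test textures use period 16 px).

## Statistics

All group comparisons follow the protocol: log10 transform first (zeros
are an error unless an explicit `offset` policy is given; negatives are
always an error), then a pooled-variance two-tailed Student t for two
groups (a Welch switch exists, off by default, and is recorded in the
result's method label), one-way ANOVA + Tukey HSD for three or more, and
Fisher's exact test (2×2, two-sided by summed probabilities) or Pearson
chi-square (no continuity correction, (r−1)(c−1) df) for categorical
tables.  Zero-margin tables are rejected.  Touch-response counts are
capped at 50 with a censoring flag at ingestion and then analyzed as
plain numbers — no survival model is fitted, matching the original
analysis; the flag is retained so a user can do better.

Half-myotomes within an embryo are treated as independent observations,
reproducing the original sampling units; the tidy tables carry an
optional `embryo_id` column so embryo-level aggregation is a `groupby`
away for users who want to avoid pseudoreplication.

## Problem sizes

The validation suite and the acceptance script use 10 phantoms per group
(20 half-myotomes each, 168×560 px), a 3-threshold sweep on one phantom
triplet, 128×128 textures with 20 seeds per texture class, exhaustive
enumeration of all 2×2 contingency tables with N ≤ 30, and 1,000-name
blinding keys.  These sizes were chosen so every statistic is estimated
well past its acceptance tolerance while the whole suite runs in about a
minute on a laptop core.

## Known limitations

- Skeleton length in pixel counts under-weights diagonal runs by √2;
  the `"weighted"` metric corrects this but changes absolute values, so
  pick one per study.
- CLAHE is not translation-equivariant (fixed tile grid); equivariance
  holds exactly for the chain downstream of contrast enhancement.
- The anisotropy factor's absolute value depends on the scale set and
  modulus floor; only comparisons under a fixed configuration are
  meaningful.
- Polygon rasterization uses a boundary-inclusive pixel-center rule;
  masks drawn by interactive lasso tools will differ along edges by up to
  half the perimeter in pixel count.
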