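# Methods

## Scope and model

`pactangio` quantifies tumor-associated microvasculature in 2D
maximum-amplitude-projection (MAP) photoacoustic angiograms of the breast
and evaluates its change under neoadjuvant chemotherapy. All analysis is
2D: ring-array PACT has much coarser elevational than in-plane resolution,
so the quantitative observables live on MAPs. The package contains three
model layers — an acoustic simulator, an image-analysis chain, and a
synthetic-scene generator — documented here in turn.

## Ring-array forward model and reconstruction

Each absorber is treated as a uniform sphere whose outgoing pressure at
distance `d` is the classic N-shaped transient
`p(t) = p₀ (d − ct) / (2d)` on `(d−a)/c < t < (d+a)/c`, with initial
pressure `p₀ = μₐ·Φ` (unit Grüneisen coefficient). Channel traces are
formed by exact bin-averaging of this piecewise-linear waveform over each
sampling interval, which suppresses edge aliasing, and superposed over
absorbers. A breast-sized background disk carrying the background
absorption plus the inclusions' *excess* absorption reproduces the full
initial-pressure field by superposition. The transducer response is a
Gaussian-envelope cosine band-pass (default 2.25 MHz center, 70%
fractional bandwidth); `fractional_bandwidth=None` selects idealized
broadband detection.

Universal back-projection evaluates `b(t) = 2p(t) − 2t·dp/dt` (central
differences; one-sided at the ends) at each pixel–element flight time and
averages over the ring with equal weights. For broadband data, `b` equals
`p₀` inside each sphere's transit window and the reconstruction is
quantitative; with the band-pass response it is edge-enhanced, as in the
physical system. **Quantitative amplitude claims (contrast recovery,
detection of the inclusion phantom) therefore use broadband detection**: a
2.25 MHz band-pass removes the low-frequency content that carries the
absolute amplitude of mm-scale absorbers, so absorption-ratio recovery
through the band-limited channel is physically impossible, not an
implementation limit.

Geometry defaults: 220 mm ring, 512 elements, 40 MHz sampling, 100 µs
record window, speed of sound 1.5 mm/µs, 0.1 mm reconstruction pixels,
grid cropped to the inclusion bounding box + 10 mm. Pixels whose flight
time exceeds the record window contribute zero and raise a coverage
warning.

Detection thresholds the lightly smoothed reconstruction at the background
mean + 3 SD and keeps 8-connected components of ≥ 2 px. The smoothing
scale defaults to 0.8 mm — just below the smallest (1 mm) inclusion — so
it acts as a matched filter; with weaker smoothing, any smooth correlated
reconstruction ripple contains enough independent fluctuation cells that
3-σ tail crossings are guaranteed regardless of amplitude scale. The
background mask used for the statistics is everything ≥ 3 mm from any
inclusion.

## Image conditioning

Fixed order: depth compensation (`× e^{0.6·depth(cm)}`), denoising,
Frangi vesselness, blending. Denoising is non-local means with the filter
strength tied to the noise level estimated from the image itself (a
noise-free image passes through unchanged); the collaborative-filtration
denoiser used on the original system is proprietary in spirit and its
exact transform stack is immaterial to the downstream geometry, so an
edge-preserving standard method fills the contract (flat-region noise is
reduced well beyond 2×). Frangi scales default to vessel radii
{0.15, 0.25, 0.4, 0.6} mm converted to pixels. The vesselness image is
self-normalized (divided by its max) and blended with the self-normalized
denoised image at 0.35/0.65. Background thresholding zeroes every pixel at
or below the maximum amplitude found outside the breast support.

## Vessel metrics

Skeletonization binarizes the blended MAP by hysteresis at (20%, 50%) of
its 99.5th intensity percentile — making the skeleton invariant to global
intensity scaling — and thins it to one-pixel centerlines. Junctions are
skeleton pixels with ≥ 3 8-connected skeleton neighbors; removing them
splits the skeleton into independent vessels, and segments under 3 px are
discarded. The relative density at a pixel is the number of *distinct*
segments intersecting the centered window (2 mm default) divided by the
border-clipped window area. "Relative" because the value depends on the
window size; the tumor-vs-healthy ordering is stable for 1–4 mm windows.

## Irregularity metrics

* Entropy: per-pixel sliding window (1 mm), histogram of 32 equal-width
  bins spanning `[0, image max]` — global bin edges keep `H` comparable
  across windows; border windows are clipped and renormalized.
* Directionality: windows are extracted with a √2 margin, rotated by
  inverse-mapped bilinear interpolation (zero fill outside the patch), and
  center-cropped before the SVD, so rotations never read zero corners from
  inside the field of view. All-zero windows take `N_SVD := 1`, hence
  `D = 0`; such windows are flagged and excluded from regional statistics,
  where `A = 1/ε` would otherwise act as a fake "maximally isotropic"
  signal. Because bilinear resampling is exact at 0°/90° and smooths at
  other angles, radially symmetric content retains a small positive floor
  in `D` (≈ 0.05–0.1); the floor is common to all windows and cancels in
  tumor/healthy contrast.
* The directionality map is evaluated on strided window centers (default
  every 3rd pixel) and nearest-neighbor upsampled: `D` is smooth at the
  1 mm window scale, so sampling it at 0.3 mm loses essentially nothing
  and cuts the dominant SVD cost an order of magnitude.
* Weighted entropy: `E = H·exp(−k/A) = H·exp(−k(D+ε))`, k = 30. Of the
  two readings compatible with the published formula, only this one
  suppresses high-directionality (healthy) windows; the alternative
  `E = H·exp(−k(A−1))` is implemented for comparison (`reading="offset"`)
  but suppresses exactly the disordered windows the method is designed to
  find.
* Segmentation: binarize `E` at mean + 1.4·SD over the breast support and
  keep the largest 8-connected component. The 1.4 multiplier was
  originally calibrated against MRI tumor sizes; no such target exists
  here, so it is a config default.
* Modulation: `M_f = (M_ae + β)·M_PA`, β = 0.07, then self-normalized;
  the additive reading is available as `reading="additive"`.
* Tumor dimensions follow the clinical caliper convention: LA is the mask
  extent along its principal axis and SA the extent perpendicular to it
  (a 10 × 5 mm rectangle reports 1.0 × 0.5 cm, not the 1.12 cm diagonal).
  Volume is summed slice areas × slice spacing when per-slice masks exist,
  else an ellipsoid approximation flagged as such.

## Statistics

Metric maps are sampled over non-overlapping windows (2 mm) tiling each
region's bounding box; a tile counts if ≥ 50% of it lies inside the region
mask, and the sample is the mean over its in-mask, defined pixels. Groups
are compared with a one-tailed Welch t-test (Satterthwaite degrees of
freedom) under the null that the ROI mean does not exceed the healthy
mean. The ROI is fixed on the baseline (T1) image and carried to later
time points; synthetic scenes are generated coregistered, so the carrying
transform is the identity.

**Known limitation — correlated tiles.** Non-overlapping tiles are not
independent samples of vascular texture: one vessel spans several adjacent
tiles. On no-tumor scenes the one-tailed p-value is therefore
over-dispersed: measured over 30 synthetic healthy scenes,
P(p > 0.05) ≈ 0.77 (density), 0.73 (entropy), 0.97 (anisotropy) instead
of the nominal 0.95. Chance anatomical clusters inside a compact ROI
occasionally mimic a lesion — the same effect the source system reports as
high-density false positives in healthy breasts. The Welch implementation
itself is exactly calibrated (empirical size 0.03–0.07 at α = 0.05 on
independent normal samples); the over-dispersion is a property of the
windowed sampling design, shared with the original method.

## Synthetic vascular scenes

The generator emulates what the scanner records, not the vasculature
itself: a 40 × 40 mm field at 0.1 mm pixels with an 18.5 mm circular
breast support. The healthy compartment draws 38 long smooth vessels as
chords under the uniform (offset, angle) line measure (near-uniform
expected density), oriented 30° ± 10° with curvature 0.12 rad·mm^-1/2,
walked from the chord entry point. The tumor compartment packs 85 short
(1.2–2.5 mm), highly tortuous (1.6 rad·mm^-1/2) microvessels into a 4 mm
radius disk placed off-center, on top of a faint smooth "blush" texture
(amplitude 0.15, correlation 0.3 mm) standing for sub-resolution
angiogenic capillaries. Vessels render with a Gaussian cross-section
(σ = radius/2, radii 0.1–0.2 mm) at unit peak amplitude, so the
compartments differ geometrically, not in brightness. The scene is blurred
with the system's in-plane point-spread function (σ = 0.11 mm),
peak-normalized, and given white Gaussian noise (σ = 0.03).
`response_fraction` removes that fraction of the microvessels (nested
subsets, so vessel count is monotone) and scales the blush down by the
same factor; healthy/tumor/noise/blush randomness lives in independent
seeded streams, so scenes differing only in response share their geometry.

What the generator does *not* model: depth-dependent fluence within the
MAP, vessel branching trees, flow or oxygenation contrast, amplitude
heterogeneity between vessels, breast deformation between visits, and
reconstruction artifacts in the scene images (scenes emulate the
post-reconstruction MAP directly). Passing ensemble tests therefore show
that the metrics respond to vascular geometry as designed — not that they
meet clinical performance on real breasts.

## Problem sizes and determinism

Default problem sizes are chosen desk-scale: 400² scene pixels, 512 × 4000
channel samples, ensembles of 20 seeds for segmentation overlap
(Dice > 0.5 in ≥ 90% of seeds) and for the baseline/complete-response
p-value pattern (p < 0.05 at baseline and p > 0.1 after complete response
for density and entropy in ≥ 80% of seeds). Every stochastic component
takes a seed; identical configuration and seed reproduce outputs
bit-for-bit.
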