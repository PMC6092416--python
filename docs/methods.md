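# Methods

This note documents the detection model, the synthetic-data generator, and
the numerical and design choices behind `deepfoci`, in enough detail to
judge what the package's tests do and do not demonstrate.

## Detection model

### Focus-flow

The core quantity is the gradient-flow coherence at a pixel `P` over the
Euclidean disk `D(P, R)` (center excluded):

    g(P)    = Σ_{P'∈D, P'≠P} ‖∇I(P')‖ · cos α(P')
    flow(P) = g(P) / Σ_{P'∈D} ‖∇I(P')‖

with `α(P')` the angle between `P' → P` and `∇I(P')`. Because `|cos| ≤ 1`
termwise, `flow ∈ [−1, 1]`; because numerator and denominator scale
identically, `flow(aI + b) = flow(I)` for any `a > 0`. These two properties
are what make the quantifier usable for deep foci: scattering attenuates the
*amplitude* of a focus by orders of magnitude but leaves the *radial
organization* of its gradients intact, and the affine invariance means the
attenuation cancels.

Implementation: gradients are central differences (one-sided at borders; a
Sobel operator is available behind the config but off by default — central
differences are the plain reading of "the gradient" and keep the brute-force
oracle simple). The disk sums are correlations with fixed kernels, evaluated
by FFT; zero-gradient pixels contribute zero to numerator and denominator,
and a pixel whose whole neighborhood has zero gradient magnitude carries the
sentinel value 0. The vectorized path is tested to 1e-9 against a direct
per-pixel double loop.

**Borders.** The raster is mirror-extended by `R` before the gradient is
taken. A truncated one-sided disk breaks the symmetric cancellation of
locally uniform gradients, so any smooth intensity ramp (autofluorescence,
vignetting) would generate spurious |flow| up to ~0.7 in an `R`-wide border
band — on a 512² frame that is a quarter of all pixels. Mirror extension
preserves the cancellation while keeping foci near edges detectable, since a
focus's own gradients are unaffected. Anti-symmetric (odd) extension was
rejected: it amplifies noise at the seam.

**Radius.** `R = 30 px` (≈ 128 µm at the default 4.27 µm/px pitch): large
enough that the disk covers the scattering blur of foci a few hundred µm
deep, small enough not to mix neighboring foci. Single radius per run; no
multi-scale pyramid.

### Candidate extraction (EXMAX with adaptive h)

Peaks are the regional maxima of the h-maxima transform (morphological
reconstruction by dilation of `raster − h` under `raster`), 8-connected,
restricted to the foreground mask, with components under `min_region_px`
(default 4) discarded as single-pixel noise. Offset invariance and count
monotonicity in `h` follow from the transform and are property-tested.

The prominence `h` is chosen per image:

1. **Noise floor.** `h_min = k · 1.4826 · median|I − median3(I)|`
   (default `k = 3`). The high-pass residual is used because the global MAD
   measures the spread of the smooth autofluorescence background, not pixel
   noise, and would push the scan's lower end above every dim focus.
2. **Scan.** 32 geometric steps from `h_min` to the dynamic range, counting
   extended-maxima components at each step.
3. **Stability plateau.** The selected `h*` is the midpoint of the longest
   run of consecutive grid points whose counts agree to within 15% (counts
   between 2 and a realism cap, default 500). Real images show a continuum
   of peak prominences, so *exactly* identical counts rarely persist for
   more than a step or two, and two degenerate regimes must be excluded:
   the count-1 tail (the global-maximum dome survives any `h` below the
   dynamic range) and the noise end of the scan, where counts in the
   hundreds drift slowly enough to fake stability. Ties between
   equal-length runs go to the higher-count run, which retains more of the
   image's structure. If no qualifying run exists the longest
   identical-count run is used and the result is flagged low-confidence;
   the full `(h, count)` scan is returned for audit in all cases.
4. **Over-counting.** The candidate set is taken at the smallest grid `h`
   whose count lies within `[count*, n · count*]` (over-counting ratio
   `n = 2`). Lowering `h` never removes true maxima, so this deliberately
   over-segments; the classifier removes the surplus. The band form of the
   rule (rather than "smallest h with count ≤ n·count*") guards against
   dips in the scan where the minimum-region-size filter drops fragmented
   maxima at very low `h`.

The same extraction runs on the preprocessed intensity image and on the
Focus-flow map of the preprocessed image (one smoothing chain — mean 3×3
then median 3×3).

### Tissue segmentation

Morphological Chan–Vese active contour (35 iterations, smoothing 3) seeded
from an Otsu threshold, followed by hole filling and largest-component
selection; a degenerate result falls back to a full-frame mask with a
warning, and a user-supplied mask bypasses segmentation entirely. For the
synthetic study the tissue fills the frame by construction, so the
experiment driver passes full-frame masks.

### Fusion and features

Gradient candidates sharing any pixel with an intensity candidate are
removed, then the surviving regions are combined (pixel-wise OR). A second
rule deduplicates: a gradient region whose centroid lies within the match
radius of an intensity region, or of a stronger (higher peak flow) gradient
region, is dropped. A blurred focus fragments into several nearby flow
maxima; without deduplication, one-annotation-claims-one-candidate labeling
marks the siblings negative with focus-like features, which measurably
poisons classifier training.

Eighteen features per candidate (fixed order, `FEATURE_NAMES`): region area,
equivalent diameter, eccentricity, solidity; disk-mean contrast (mean over
an `R/2` disk at the centroid minus local background); mean, max, peak
contrast, SD and saturation fraction of the region intensity; mean flow, max
flow, flow contrast; radial log-intensity decay slope fitted over `1.5R`;
mean gradient magnitude on the region boundary; centroid distance to the
mask edge (µm); provenance flag; local candidate density within `3R`. Local
background is the median over a ring at radii `1.2R–1.8R` from the centroid
(pushed outward for regions larger than `R`): a ring hugging the region
would sit inside the scattering blur of a deep focus and erase its
contrast. The exact feature list is a design choice of this package; the
extractor sits behind one function so an alternative list can be swapped in.

### Classifier

Per-feature z-scoring (training statistics), PCA keeping the smallest
number of components explaining ≥ 95% of variance, RBF-kernel SVM. `C` and
`γ` are selected by leave-one-image-out search over exponentially spaced
grids (defaults `C ∈ 2^−5 … 2^15`, `γ ∈ 2^−15 … 2^3`, powers-of-two steps
of 2), scoring each combination by the mean held-out candidate-level
detection accuracy `TP/(TP+FN+FP)`; ties go to the smallest `C`, then the
smallest `γ`. The final model is refitted on all images and serializes to
versioned JSON (scaler statistics, PCA basis, support vectors, dual
coefficients); the decision function is evaluated directly from those
arrays, so save/load round-trips reproduce predictions exactly. No class
weighting and no probability calibration. Labels come from point
annotations: a candidate is positive iff its region contains an annotation
or it is the nearest candidate centroid within the match radius (default
`R`); exact ties go to the lower region id.

### Evaluation

Detections and reference points are matched one-to-one greedily by
ascending distance within the match radius (validated against exhaustive
assignment on small instances — with sparse foci the two coincide).
Accuracy `TP/(TP+FN+FP)`, precision and recall follow; undefined metrics
(all-zero counts) are reported as missing, never as 0. Depth curves bin
ground-truth foci in 50 µm slabs and report percent detected per occupied
bin. Bland–Altman agreement between two per-image count sets uses
`bias ± 1.96 · SD` (sample SD) for the 95% limits.

## Synthetic-data generator

The simulator renders wide-field images of fluorescent cell clusters in a
scattering slab, with ground truth. What it emulates, per stage:

- **Phantom.** Clusters uniform in the volume; cells per cluster uniform in
  [1, 50]; per-cell fluorophore concentration uniform in [0.5, 1.5]
  relative units; cluster radius `7 µm · n_cells^(1/3)` (cells packed into
  a ball). Each cluster is assigned to its nearest 25 µm depth plane
  (cluster radii are at most ~26 µm, about one plane) and rasterized as a
  Gaussian spot with σ = radius/2 whose integral is the cluster's total
  fluorophore.
- **Background.** Gaussian random field: white noise smoothed with a
  Gaussian of σ = ℓ/2 px so the autocovariance is `exp(−r²/ℓ²)` (1/e at
  the configured correlation length ℓ, default 1 mm), scaled to the
  configured mean (default 500 intensity units) and relative SD (default
  0.3), floored at 10% of the mean.
- **Scattering PSFs.** Per-depth Monte Carlo transport: isotropic point
  source, exponential free paths at rate `µs + µa`, Henyey–Greenstein
  phase function, absorption as multiplicative survival weight, Russian
  roulette below weight 1e-4, photons binned where their path first crosses
  the surface. Optics defaults: `µs = 10 mm⁻¹`, `g = 0.9`,
  `µa = 0.1 mm⁻¹` (generic soft tissue), 25 µm planes over the slab, 10⁴
  photons per plane. Refractive-index mismatch at the surface is ignored.
  Two deliberate departures from textbook "bin every exit":
    - **Collection cone.** Only photons exiting within 20° of the surface
      normal enter the kernel. An isotropic emitter under a free surface
      otherwise produces a Cauchy-like exit fan of width ~`depth · tan θ`
      that no low-NA objective images; with the cone, kernels are
      delta-like at the surface and spread to ~160 µm rms at 450 µm depth,
      with peak decay of order 10² over the slab. Kernels are normalized by
      the cone's solid-angle fraction, so an unscattered surface emitter
      sums to 1 and deeper kernels to the relative transmission (shallow
      sums may slightly exceed 1 from in-cone in-scattering). Setting the
      cone to `None` restores pure transport, where photon conservation at
      `µa = 0` holds and is tested (to 5%: the lateral first-passage
      distribution is heavy-tailed, so a few percent of weight falls beyond
      any finite window or event cap).
    - **Finite window.** Exits beyond the kernel half-width are dropped;
      conservation tests use a wide, coarse window.
- **Microscope and camera.** In-focus Gaussian PSF with
  `σ = 0.21 λ/NA` (NA 0.04, λ 520 nm), normalized to unit sum. One fixed
  camera gain per experiment, anchored so a reference 25-cell surface
  cluster sits at twice the 16-bit saturation — big shallow clusters clip,
  as they do in practice. Poisson shot noise, Gaussian read noise, clipping
  at 65535, integer quantization.

### Calibration of the unstated conditions

Three scales are not derivable from first principles and were calibrated to
the qualitative regime the method is designed for — shallow foci saturate
the sensor, mid-depth foci are clear unsaturated peaks, deep foci sink into
the detector noise yet remain flow-coherent — and then frozen:

- `focus_brightness = 1e4` background-intensity units per fluorophore unit
  (a single cell at the surface is a clear spot; a 25-cell cluster
  saturates).
- `read_noise_sd = 800` counts ≈ 1.2% of full range (`sat/σ ≈ 80`, an
  ordinary color-camera/short-exposure regime). This is the binding
  constant: with a near-noiseless sensor the intensity pipeline alone
  detects every focus the gradient pipeline can, and the gradient
  pipeline's contribution — the point of the method — cannot be observed at
  any optical setting, because the depth decay (~10²–10³) is finite while a
  16-bit noise floor of 10 counts leaves deep foci at 30–90 SD.
- The in-silico study runs at desk scale: 20 images (10 train / 10 test),
  512×512 px covering 2×2 mm of the 0.5 mm slab (pixel pitch 3.91 µm/px),
  40 clusters per image, with the sPSF stack shared across images and a
  6×6 powers-of-four hyper-parameter subgrid spanning the same exponent
  ranges as the full classifier grids.

### What the generator does not emulate

No excitation-path transport (uniform excitation assumed), no
refractive-index mismatch, no polarization or time resolution, no cellular
texture in the autofluorescence, no vignetting or illumination falloff, no
tissue-boundary geometry (the slab fills the frame), and cluster shapes are
isotropic Gaussians rather than irregular cell packings. Passing tests
therefore show that the pipeline behaves as designed under controlled
scattering, background and noise — not that the specific accuracy numbers
transfer to any particular real tissue, rater or camera. Statistics
reported for real data (per-image accuracy against a rater, Bland–Altman
limits of agreement between raters) are computable from any image +
annotation set via the evaluation module.

## Numerical choices and degenerate inputs

- Flow denominator floor `max(‖∇I‖_max, 1) · 1e−12`: below it the sentinel
  0 is returned (constant images are identically 0). FFT round-off outside
  [−1, 1] is clipped.
- Flat rasters: `exmax` returns an empty set; `heuristic_h` raises
  ("flat raster"); segmentation falls back to a full-frame mask with a
  warning.
- Annotation ties (two candidates equidistant): lower region id wins —
  deterministic.
- Matching ties (equal distances): detection index, then reference index.
- Grid-search ties: smallest `C`, then smallest `γ`.
- The h-grid lower bound is clamped to at most half the dynamic range and
  at least 1e−6 of it.
- A filtered raster may overshoot the saturation ceiling by float
  round-off; overshoot within 1e−9 relative is clipped, larger overshoot is
  an error.
- Every stochastic stage takes an explicit seed; the experiment driver
  derives per-image sub-seeds from one master seed, and identical seeds
  reproduce byte-identical reports.

## Known limitations

- The adaptive-h plateau rule and the 18-feature list are this package's
  operationalizations of loosely specified components; both are exposed
  (audit scan, single extractor function) so alternatives can be swapped
  in.
- Candidate-level recall is bounded by the over-counting budget: foci whose
  prominence ranks below `n × count*` in both pipelines are unrecoverable
  downstream.
- The Monte Carlo kernels at 10⁴ photons are noisy at depth; the rendered
  deep-focus halos inherit that speckle. Increasing photons per plane
  smooths them at linear cost.
- Runtime is dominated by the 32-step EXMAX scans (two per image); a 20
  image study completes in a few minutes on one CPU without any
  parallelization.
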