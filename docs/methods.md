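# Methods

This note documents the models, numerical choices and limitations behind
`filasim`.  Everything stated here is computed by the test suite or the
example scripts; nothing is quoted from external measurements.

## Filament geometry

A filament is a planar polyline of n segments.  The total length L is
drawn first from a truncated-positive Gaussian (rejection sampling, cap
1000 redraws); segment lengths ℓ_k come from a second truncated-positive
Gaussian and are drawn until the cumulative length reaches L, the last
segment being shortened so Σℓ_k = L exactly.  L is therefore exact and n
emergent — the alternative (fixing n) would distort the length law.

Directions evolve as ϕ_k = ϕ_{k−1} + B_k·η_k with η_k ~ Gamma(shape,
scale).  The sign process starts at B_0 ~ Uniform{−1, +1}; at each step it
flips with probability `flip_prob` until `max_flips` flips have occurred,
after which it freezes.  This is the simplest process satisfying both the
per-step flip probability and the global budget Σ|B_k − B_{k−1}| ≤
2·max_flips.  The seed orientation ϕ_0 is uniform on [0, 2π), and the
first segment carries no bend (η_0 := 0), so ϕ_0 is exactly the initial
direction.  Curvature per unit length is controlled by shape·scale/μ; the
test suite verifies a Spearman ρ > 0.9 monotone response.

Scenes draw a filament count as round(truncated-at-0 Gaussian) — validated
against a numeric-integration oracle of E[round(X) | X ≥ 0] — and place
seed origins uniformly on the canvas.  Filaments may leave the canvas;
clipping happens at rasterization, mirroring real frames where filaments
cross the field of view.

Coordinate convention everywhere: continuous (x, y), origin at the center
of the top-left pixel, x rightward, y downward.

## Rasterization and rendering

A pixel belongs to a filament's skeleton mask iff the polyline intersects
the pixel's closed unit square (supercover).  The implementation is an
inclusive Liang–Barsky slab test of every candidate square; tests verify
exact set equality against a brute-force geometric oracle on hundreds of
random polylines, including corner touches.

The ideal image is I = A·(M ∗ psf) + B with a unit-sum isotropic Gaussian
PSF truncated at 4σ.  A is signed — IRM filaments are dark, so the default
contrast is negative, but the tuner may discover either polarity.
Convolution is zero-padded; borders therefore darken slightly unless
vignetting compensates — a documented contract that the domain tuner
absorbs.  Nucleation seeds are the first `seed_len` of arc length of each
filament, rasterized into a shared support, PSF-blurred and added to the
red channel only; green and blue always equal the base image.

Ground-truth instance masks are the rasterized skeletons dilated by a
1-px disk.  Skeleton-only ground truth would make the SKIoU numerator
degenerate under 1-px shifts (the mask intersection of two disjoint 1-px
lines is empty); the 1-px radius gives instances a physical width
comparable to the rendered apparent width at the default PSF.  The radius
is a constant in `filasim.rendering`; its effect on scores is a known
sensitivity.  Filaments whose in-canvas skeleton has fewer than 2 pixels
are dropped from both image and masks — sub-pixel fragments are
unlabelable.

## Degradation operator

Stages run in a fixed order: multiplicative low-frequency background
field → distractor spots → Gaussian blur → vignetting → multiplicative
speckle → Poisson shot noise → additive Gaussian noise → per-channel gain
jitter (RGB only) → clip to [0, 1].  Signal-dependent noise must act on
the already-structured image, and a fixed order makes outputs
reproducible.  Conventions:

* `photon_scale = 0` is the sentinel for "Poisson off"; otherwise the
  image becomes Poisson(I·c)/c, giving variance I/c (verified within 5%
  against the analytic law).
* The background field is 1 + amp·G with G white noise smoothed at width
  `bgfield_scale`, recentred to zero mean and unit max-abs, so the field
  is bounded by 1 ± amp and its correlation length grows with the scale.
* Vignetting is a radial cosine falloff: 1 at the exact center,
  1 − strength at the farthest corner.
* Distractor spots are Poisson-many blurred disks with uniform radius and
  signed gain; they are never added to the ground truth.  Irregular
  (non-disk) distractor shapes are a known limitation.
* A zero-amplitude configuration returns the input bit-exactly.

## Prediction dialects and unified pre/postprocessing

Segmenters return per-instance boolean stacks, integer-labeled maps, or
anchor-point chains.  Everything is normalized to stacks for scoring;
anchor chains are converted by an interpolating parametric cubic spline
(smoothing 0) sampled at 4 points per pixel of arc length, falling back
to piecewise-linear joining below 4 distinct anchors.  A straight-line
conversion is kept as a separate API because the curvature-preprocessing
path is defined over straight joins; both coincide for 2-point chains.

Postprocessing filters predicted instances by skeleton length and pixel
area against bounds derived from the ground truth (min/max expanded by a
relative margin, default 10%; anchor chains are filtered by chain length
only).  The margin exists because exact-min/max filtering discards
borderline-true instances; with a single GT instance the bounds collapse
to ±margin of that instance, so small tuning sets may want a wider margin
(the harness exposes it).  Labeled-map inputs come back from
postprocessing as mask stacks; filtering labels cannot preserve the
original labeling losslessly.

## Segmentation metrics

SKIoU = 2·|S(pred ∩ gt)| / (|S(pred)| + |S(gt)|), intersection before
thinning, value capped at 1, and an empty-vs-empty pair defined as 0 (such
pairs are excluded from aggregation).  Two aggregation protocols coexist
deliberately, because they answer different questions:

* mean SKIoU — for each GT instance the best prediction (non-exclusive),
  0 when missed; penalizes false negatives but not false positives.
* AP/F1 — greedy one-to-one matching in descending SKIoU order with
  deterministic (gt, pred) index tie-breaks, at thresholds 0.50…0.95 in
  steps of 0.05.  Predictions carry no confidence scores, so AP@τ is
  defined as TP/(TP+FP+FN), the convention used in cell-segmentation
  benchmarks; F1@τ = 2TP/(2TP+FP+FN).  Greedy matching is not guaranteed
  optimal; tests assert it never exceeds the exhaustive-assignment
  optimum on small instances.

Dataset scores are macro-averages (per image, then across images).
Images with no GT instances are undefined for mean SKIoU (and for AP/F1
when there are also no predictions) and are excluded from those averages
rather than counted as 0 — otherwise an empty frame would corrupt an
otherwise perfect self-evaluation.

## Biological statistics

Instance length uses the skeleton pixel count |S(M)| as the benchmark
proxy.  That proxy is orientation-biased (a 45° line has ~0.71·L pixels),
which is acceptable for comparing predictions against ground truth
measured the same way, but not for geometric checks; a separate
`skeleton_arc_length` (summed Euclidean steps along the ordered skeleton)
serves those.

Curvature: skeleton pixels are ordered by greedy nearest neighbor
(starting at an endpoint when one exists, else at the lexicographically
smallest pixel; ties lexicographic), a parametric spline is fitted, and
κ(u) = |x′y″ − y′x″|/(x′² + y′²)^{3/2} is averaged over a uniform grid
with one sample per skeleton pixel (zero-speed samples excluded).  Two
numerical choices matter:

* **Quantization-matched smoothing.**  Skeleton pixels are integer
  positions; an exactly interpolating spline through them measures the
  rasterization staircase, not the filament (measured: ~0.4 px⁻¹ on a
  digital circle of true curvature 0.02 px⁻¹).  The spline is therefore
  fitted with residual budget n/6 — the expected summed squared
  quantization error of n pixel centers (uniform ±1/2 noise, variance
  1/12 per axis).  The estimate is insensitive to this budget over an
  order of magnitude.  For continuous sub-pixel paths (anchor chains,
  analytic curves) `fit_curve` defaults to exact interpolation.
* **Periodic closed loops.**  A skeleton with no endpoints is a closed
  loop; it is fitted with a periodic spline so the arbitrary cut point
  does not create end artifacts.

Measured accuracy: digital circles of radius 25/50 px recover 1/R within
0.4%/0.12%; straight filaments at arbitrary angles measure ≈ 5·10⁻⁴ px⁻¹
on average.  That figure is the estimator's absolute noise floor:
curvature differences below it (and relative comparisons for shapes with
κ ≲ 0.01 px⁻¹) are not resolvable.  Branched skeletons (merged
predictions) are still ordered greedily; their curvature may be inflated —
documented behavior, not an error.

KL divergence between two samples uses histograms on shared linear bins
spanning the pooled min–max (50 bins by default), with additive smoothing
1e-10 added to both count vectors before normalization so empty bins stay
finite, and the natural logarithm.  Identical samples give exactly 0.
`pixel_size_um` has no default; micrometer-denominated outputs require it
explicitly, pixel-denominated outputs are always available.

## Domain tuner and few-shot harness

The tuning objective generates one image per trial from the candidate θ
(seeded), embeds it and each reference frame, and takes the maximum
cosine similarity over references — so an accepted θ must be plausible
for at least one reference.  One draw per trial keeps the loop cheap; the
number of draws is configurable.

The built-in embedding is a deterministic handcrafted feature vector
(64-bin intensity histogram, gradient-magnitude statistics, 16-bin
radially averaged log power spectrum).  It separates background level,
contrast polarity, texture scale and noise amplitude without any model
weights, which keeps the package testable offline; a deep
vision-transformer backend can be plugged in behind the same
`EmbeddingBackend` contract and is the recommended choice when weights
are available.

Samplers sit behind one interface: `"random"` is seeded uniform search
(exactly reproducible under the master seed); `"adaptive"` uses a
tree-structured Parzen estimator through `optuna` when that optional
dependency is importable and otherwise falls back to random search.  The
harness's correctness never depends on the sampler.

`adapt_segmenter` reuses the trial loop to maximize the mean over tuning
images of mean SKIoU after unified postprocessing.  Segmenter exceptions
score the trial 0 and are logged; third-party segmenters crash, and the
harness must survive that.

## Synthetic data as a test bed — what it does and does not show

The generator's default θ targets the regime the evaluation suite is
meant for: 512×512 frames, a truncated-Gaussian filament count with mean
11.28 and SD 5.1, total lengths 130 ± 65 px (at a nominal 0.1 µm/px this
corresponds to microtubule lengths on the order of 13 µm), segment
lengths 3 ± 1 px so that polylines render as smooth curves, dark contrast
−0.35 on background 0.55, PSF σ = 1.2 px, and mild defaults for every
degradation amplitude.  Tests that pass on these synthetic frames
demonstrate correctness of the geometry laws, rendering contracts and
metric implementations.  They do not demonstrate realism of any
particular real microscope: interference fringes, depth-dependent
contrast reversals, elongated debris and temporal dynamics are not
modeled, and the handcrafted embedding is far weaker than a learned one
at separating such effects.  Fitting θ to actual reference frames (and
judging the result) remains the user's responsibility.

Reduced problem sizes used by the test suite (small canvases, one-to-few
filaments per frame, tens-to-hundreds of trials) are the package's own
choice of test scale; the full-scale defaults are exercised by the
20-frame self-evaluation in `scripts/acceptance.py` and the
6600-record assembly test.

## Known limitations

* No filament–filament interaction, no dynamic instability, single-frame
  only (no video containers or tracking).
* Distractors are blurred disks; no irregular or elongated artifacts.
* No physical optics (interference, 3D PSF); per-filament intensity does
  not vary beyond the global contrast.
* The skeleton pixel-count length proxy is orientation-biased (see above).
* Greedy AP/F1 matching is a convention, not an optimum; confidence-ranked
  AP curves are out of scope because the supported dialects carry no
  scores.
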