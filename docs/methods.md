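# Methods

This note documents the models, parameter choices and numerical
conventions behind `wristseg`, and what its synthetic benchmark does and
does not demonstrate.

## Phantom generator

The generator emulates the salient obstacles of wrist MRI rather than
its physics. Each phantom is a set of piecewise-constant regions —
convex ellipses for bones, an outer-minus-inner-ellipse crescent for
cartilage, one designated lesion — rasterized with pixel-center
point-in-shape tests in painter's order (later regions overwrite
earlier ones), multiplied by a smooth bias field, plus additive noise,
clipped to [0, 1]. Ground truth is derived from the noiseless label
image: a truth-edge pixel is one whose region label differs from at
least one 4-neighbor (so boundaries are marked on both sides and form
closed curves), and the lesion mask is the lesion's final label
support.

Default study conditions (`default_wrist_spec`): 128×128 pixels; three
bone regions with means 0.58/0.62/0.66 — within 0.1 of each other to
mimic the near-identical signal of radius, scaphoid and lunate; a
cartilage crescent a few pixels thick (well under a tenth of the image
width); a lesion ellipse inside the radius at +0.28 contrast; bias
amplitude 0.08; additive zero-mean Gaussian noise with σ = 0.03.
No quantitative noise or inhomogeneity characterization of real wrist
cohorts was available, so these are realistic stand-ins chosen once,
not calibrated to any dataset. Geometry is jittered slightly per seed
so a cohort is not one repeated image.

Choices made where the design was open:

* **Noise model** — additive Gaussian by default; a Rician option
  (magnitude of a complex signal with iid Gaussian components, the
  physically faithful MRI model) is available but not default, since
  the additive model suffices to exercise the pipeline.
* **Bias field** — a random second-order 2-D polynomial surface affinely
  rescaled to exactly [1−A, 1+A]; second order is the lowest order that
  produces the slow corner-to-corner shading typical of surface-coil
  inhomogeneity.
* Coordinates are row-major, origin top-left, 0-based, pixel centers at
  integer coordinates — consistently across the package.

What the phantom does **not** model: T1/T2 contrast physics, k-space
and motion artifacts, partial-volume effects, anatomical shape
variability, 3-D structure. Passing benchmarks here demonstrates the
pipeline's internal correctness and its behavior under controlled
noise/bias — not clinical performance.

## Canny detector

* Standard isotropic Gaussian smoothing, kernel truncated at radius
  ⌈3σ⌉ and renormalized to unit sum; reflect padding (avoids spurious
  border edges).
* Gradients by central differences in the interior and one-sided
  differences at borders.
* Non-maximum suppression quantizes the direction to four sectors
  (0°, 45°, 90°, 135°) without sub-pixel interpolation, and keeps a
  pixel only when **strictly** greater than both directional neighbors;
  ties suppress, so constant fields yield no edges. Out-of-image
  neighbors count as zero. This is simpler and exactly testable against
  a double-loop oracle; interpolating variants shift some edges by one
  pixel.
* Hysteresis: strong = NMS ≥ t_h, candidates = NMS ≥ t_l; an edge is any
  candidate 8-connected to a strong pixel (implemented via connected
  component labelling; verified against a BFS flood-fill oracle).
  Ratios ≤ 1 collapse the double threshold to a single threshold at
  t_l, which keeps the historical ratio grid (0.3 … 1.8) well defined.
* Thresholds can be absolute on the NMS magnitude or relative
  (a fraction of the per-image maximum). The pipeline defaults —
  σ = 1.4, relative t_l = 0.12, ratio 1.8 — were calibrated on default
  phantoms (no absolute gradient scale is canonical for arbitrary
  inputs) and are exposed in `PipelineConfig`.

## Particle swarm optimizer

Global-best PSO with the bare velocity update (no inertia coefficient,
i.e. w = 1) as the default, matching the classical formulation this
package follows; because that variant never damps velocities, three
safeguards apply: velocities are clamped per dimension to the box
width, positions are clipped to the box, and a clipped dimension's
velocity is zeroed (prevents boundary sticking). A constant or linearly
decaying inertia is exposed (`inertia`, `inertia_final`), and the
SVM-tuning default uses 0.9 → 0.4 decay, the standard convergent
schedule. ρ₁, ρ₂ are uniform on [0, 1] per particle and dimension
(descriptions of PSO occasionally conflate "random on [0,1]" with
normality; a normal distribution cannot have range [0,1], and uniform
is the standard choice). Minimization convention throughout.

One ambiguity was deliberately not guessed at: PSO is sometimes
described as also *extracting* edge features, but no objective function
for that role exists; here the swarm only tunes (C, γ). The feature
descriptor is fixed (below).

## Kernel SVM

Soft-margin dual with box constraint 0 ≤ κ ≤ C (the hard-margin dual
admits no "penalty factor"; the box is what makes C meaningful, and C
is what the swarm tunes). Solver: sequential minimal optimization with
maximal-violating-pair selection on the precomputed kernel matrix;
stopping tolerance 1e−7 on the KKT violation gap (1e−4 during
cross-validation inside tuning, where speed matters and ±1 support
vector does not), hard iteration cap with a diagnostic error on
non-convergence. The offset is averaged over unbounded support vectors
(fallback: midpoint of the final violating pair). RBF
exp(−γ‖a−b‖²) is the default kernel; the linear kernel is retained for
analytic tests and recovers the explicit primal weights.

Edge-pixel descriptor (7 components): window mean and population std
(5×5, reflect-padded), gradient magnitude, cos θ, sin θ, normalized row
and column. Minimal, local and orientation-aware; the positional
components let the classifier exploit the roughly consistent anatomy of
the phantom cohort. Training labels: an edge pixel is lesion-positive
iff within Chebyshev distance 1 of the lesion-mask boundary.

Lesion-mask reconstruction: 3×3 morphological closing of the positive
edge pixels, then interior hole filling. This assumes the classified
lesion boundary is (nearly) closed — true for the phantom regime; a
fragmented boundary degrades the mask rather than failing loudly, which
is a known limitation. Class imbalance is handled only by stratified
folds and stratified subsampling of the training pool.

## Metrics

* MSE, PSNR = 10·log₁₀(pe_max²/MSE) with a +inf sentinel for identical
  images (serialized as `null` in JSON).
* Pratt FOM with the standard scaling ρ = 1/9.
* SSIM over 8×8 sliding windows, unit stride, exponents α = β = γ = 1,
  constants C₁ = (0.01·L)², C₂ = (0.03·L)², C₃ = C₂/2 with L = pe_max,
  population statistics.
* Edge continuity CI: 8-connected segments; a segment's score is the
  fraction of its pixels with ≥ 2 edge neighbors; CI is the
  size-weighted mean, capped just below 1 to respect its [0, 1) range.
  The neighbor-degree definition was chosen because it is the simplest
  measure that is 1⁻ on closed 1-pixel-wide curves, 0 on isolated
  pixels, and penalizes endpoints of open curves.
* Edge credibility BI: fraction of detected edge pixels within
  Chebyshev distance 1 of a truth edge pixel. Both CI and BI are
  isolated behind this module's interface so alternative definitions
  can be swapped.
* Acc, Sen, Spe, DSC from per-pixel confusion counts; a zero
  denominator yields NaN rather than a silent 0.

## Benchmark protocol and problem sizes

`run_benchmark(n, config)` generates n seeded phantoms, trains on the
first `n_train_phantoms` (default 3) and evaluates the held-out rest —
per-phantom self-training was rejected as an optimistic protocol.
Fidelity metrics (PSNR/MSE/SSIM) compare the noiseless phantom image
with the pipeline's Gaussian-smoothed image (its denoising stage);
FOM/CI/BI score the detected edge map against the true boundaries; the
diagnostic scores compare the reconstructed lesion mask with the true
lesion mask pixelwise.

Default problem sizes — 128×128 phantoms, n = 10, training pool
subsampled to ≤ 600 edge pixels (stratified, keeping at least a third
positives), swarm of 8 particles × 10 iterations over 3-fold CV — keep
a full benchmark around half a minute on one CPU while leaving the
tuning landscape non-trivial. A single master seed derives named
substreams (phantom cohort, swarm, fold assignment, subsampling) via
`SeedSequence`, so runs are bit-reproducible from the config snapshot
and stages are independently reseedable.

## Known limitations

* Phantom realism as above; absolute metric levels on phantoms do not
  transfer to patient data.
* The positional feature components assume a roughly consistent
  geometry between training and test images.
* Binary lesion/non-lesion only; no multi-class lesion typing, no
  probability calibration.
* CI and BI are this package's concrete definitions of otherwise
  under-specified indices; comparisons with other implementations
  should check definitions first.
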