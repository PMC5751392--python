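# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package — what the code computes and why it computes it
that way.

## Conventions

* Arrays are (axial sample × scan line); depth grows with the row index,
  sample `i` sits at depth `z = depth_offset + i·c/(2 fs)`.
* Displacements are kept in axial samples / scan lines internally and
  converted to metres only for reporting.  Positive axial displacement is
  motion toward greater depth.
* All displacement fields are expressed in the **transducer frame**: the
  transducer rides on the compressed top surface, so displacement is zero at
  the top of the image and accumulates with depth, reaching `-compression`
  (motion toward the transducer) at the fixed bottom.  This is what an
  echo-delay estimator actually observes, it is the regime in which the
  chained 1D estimator's zero initialization of the first window is sound,
  and it is why the coarse search ranges are enlarged for deeper windows.
* Strain is reported compression-positive (the displacement gradient is
  negated once, in `strain_map`).

## Displacement estimation

### Coarse stage

Block matching maximizes zero-normalized cross-correlation (NCC) between
envelope windows.  Three levels run on envelope planes decimated by 8, 4
and 2:

* **Level 1** — nine windows on a 3×3 grid at depth/width fractions
  {1/6, 1/2, 5/6}, searched exhaustively.  The axial search half-range is
  `0.75 · expected_max_strain · frame_depth` at the top row, grown by 50%
  per row (displacement accumulates with depth), so the bottom row covers
  1.5× the largest displacement the configured strain can produce.
* **Levels 2 and 3** — 7×11 windows, then windows tiling the whole frame at
  50% overlap.  Both use *following tracking*: the reference point moves
  greedily to the best-correlated point of its full 5×5 neighbourhood until
  it is a local maximum or leaves the search region.  Within a column, each
  window's converged point seeds the next window's start (*delivering*).
  Window sizes follow the fixed shrink rules (level 2 = 1/3 of level 1,
  level 3 = 1/2 of level 2, each in its own scale's samples).

The level-1 calculation window defaults to 15 carrier wavelengths × 18
lines.  The shrink rules then leave level-3 windows of ≈1.2 wavelengths ×
3 lines — about four independent speckle cells, the practical minimum.
Smaller level-1 windows (e.g. 10λ × 10 lines) leave level-2/3 windows with
so few speckle cells that false NCC peaks appear in several percent of
windows.

Two error-correction mechanisms keep the coarse grid consistent with the
spatial continuity of a quasi-static deformation:

* windows whose peak correlation falls below `valid_floor` (default 0.5)
  are invalid and refilled from the median of valid neighbours.  Measured
  genuine matches score > 0.7 at these window sizes while false peaks in
  decorrelated regions score 0.1–0.45, so 0.5 separates them cleanly;
* windows deviating from their 3×3 neighbourhood median by more than half
  the fine-stage capture range (a quarter carrier period, converted to the
  level's units) are rejected and refilled likewise.

Between levels and onto the fine grid, displacements are bilinearly
interpolated; outside the source grid's hull they are **linearly
extrapolated** from the edge cells.  Nearest-edge clamping was tried first
and left initialization errors near the frame top/bottom larger than the
fine stage's capture range, because displacement keeps growing toward the
frame edges.

The final lateral displacement is Savitzky–Golay smoothed along the lateral
direction (window 9 grid columns, order 2) and values below 0.25 lines are
zeroed: sub-quarter-line shifts are below the lateral sampling and shifting
by them would only inject noise.

### Fine stage

The phase zero-crossing update in baseband form is

```
tau <- tau - (1/w0) * arg[ exp(j w0 tau) * Σ_t x1b*(t) · x2b(t + tau) ]
```

with `w0 = 2π f0/fs` rad/sample and `x2b` evaluated at fractional lags by
complex linear interpolation of the baseband (the baseband is smooth at the
speckle-correlation scale, so linear interpolation contributes ≲0.02
samples of bias; an explicit oversampled sum would cost memory for no
measurable gain).  Iteration stops when the step falls below `tol = 1e-3`
samples or after `max_iter = 20` iterations; on clean signals it converges
in ≤5.

The estimator's capture range is half a carrier period (`π/w0` = 8 samples
at 120 MHz / 7.5 MHz): initialized further from the true delay than that,
the iteration converges to a phase zero one full period (16 samples) away.

* **Hybrid (modified) form** — window length 1.5 wavelengths (24 samples),
  75% overlap; every window initialized from the interpolated coarse axial
  estimate; the post line replaced by the line at
  `line + round(lateral displacement)` (no inter-line interpolation:
  lateral pitch is ~20× the axial pitch, so sub-line interpolation is
  low-yield).  Windows are mutually independent.  Afterwards, unconverged
  windows are replaced by the 3×3 median of converged neighbours, and
  windows deviating from their 5×5 median by more than a quarter period —
  the signature of a phase-wrapped alias — are replaced by that median
  (up to 3 sweeps).
* **Chained 1D baseline** — per line, window k starts from window k−1's
  estimate, the first window from zero; no lateral handling, no alias
  correction.  This reproduces the baseline's characteristic failure:
  once a decorrelated window slips a carrier period, every window below it
  inherits the error.
* **Downsampled 1D baseline** — the chained form on baseband decimated by
  `ds_rate` (default 4), with the window length kept in decimated samples,
  so it evaluates `ds_rate`× fewer windows spanning `ds_rate`× more depth
  each; estimates are rescaled to finest-sample units.

## Strain and metrics

LSQSE: at each position the strain is the slope of the least-squares line
fitted to displacement-vs-depth over a centered kernel of 41 fine-grid
windows (≈1.6 mm); exact on linear displacement, and the kernel width
trades axial resolution against variance at the default 75% window overlap.

CNRe uses circular ROIs of radius 1.5 mm: the inclusion ROI at the
inclusion center, the background ROI at the same depth offset 6.5 mm
laterally — safely inside the 3 mm inclusion and safely outside it.  The
strain ratio is reported background/inclusion so the phantom's configured
contrast of 5 reads as ≈5.

The binary strain image thresholds at the whole-map mean strain (black =
below the mean).  Note a structural property of the uniform-plate
compression geometry: the depth integral of axial strain along *every*
scan line equals the applied compression, so every A-line's mean strain
equals the global mean and roughly half of the background lies below the
threshold in any faithful 2-D field.  The mean-thresholded area ratio of
the ground-truth field is therefore ≈0.48, far above the geometric
inclusion fraction π r²/(W·H) ≈ 0.071 that serves as the reference line in
study plots.  The inclusion is nevertheless cleanly separable — its strain
is ~5× below background — and thresholding at half the mean recovers the
geometric fraction within a few percent on the truth field.

## The phantom simulator

What it emulates: a 20 × 20 mm plane-strain block, 3 mm-radius stiff
circular inclusion at the center, Poisson ratio 0.495, density 1000 kg/m³,
inclusion modulus 100 kPa, uniaxial top compression 0.3–0.8 mm with the
bottom supported; a 7.5 MHz linear array sampled at 120 MHz with 128 lines
spanning the 20 mm width (pitch = width/128 ≈ 0.156 mm so the image zone is
self-consistent).

* **FEM** — bilinear quadrilateral elements on a regular mesh (default
  80×80), plane strain.  The volumetric (λ) term is integrated at one
  point, the shear (μ) term at 2×2 Gauss points (selective reduced
  integration); full integration locks at ν = 0.495.  Boundary conditions:
  top edge driven down by the compression with free lateral slip, bottom
  edge axially fixed on frictionless rollers with one center node pinned
  laterally, sides traction-free.  For a homogeneous block this reproduces
  the uniform closed-form field to machine precision (a fully clamped
  bottom has no uniform closed form near incompressibility and distorts
  the interior field by ~8%).  Mesh convergence: the contrast ratio moves
  <2% between 40×40 and 80×80 meshes.
* **Contrast calibration** — the background modulus is searched (Brent)
  until the FEM background/inclusion mean strain ratio over the metric
  ROIs equals the configured contrast within 2%; with the inclusion at
  100 kPa and contrast 5 this yields ≈12.9 kPa.  The ratio is invariant to
  the applied compression (linear elasticity), so one calibration serves
  all strain levels.
* **Scatterers** — Poisson count at 20/mm² (≈8000), uniform positions,
  standard-normal amplitudes; the post frame reuses the same realization
  displaced by the interpolated FEM solution.
* **RF model** — each scatterer contributes a Gaussian-enveloped carrier
  pulse (60% fractional −6 dB bandwidth) at its round-trip delay, weighted
  by a depth-invariant Gaussian lateral beam (σ = 0.4 mm), plus white noise
  at 30 dB SNR.  These unstated acquisition parameters are typical
  linear-array values and are fixed in the config.

What it does **not** emulate: diffraction and depth-dependent focusing
(transmit focus / dynamic receive), element-level delay-and-sum, frequency-
dependent attenuation, out-of-plane motion, nonlinear elasticity.  The
consequence is that simulated speckle decorrelates more gently than
physical data, so absolute CNRe values here are optimistic; the *relative*
comparison between algorithms — which shares every modelling idealization —
is the meaningful output, and passing tests demonstrate correctness of the
estimators on this model, not clinical performance.

## Problem sizes and runtimes

The study scale is the native one throughout: 3118 × 128-sample frames,
80×80 FEM mesh, ≈65 000 fine windows per frame pair.  One hybrid pipeline
run takes ~4 s on one CPU, the chained baseline ~1 s, a pair simulation
~1 s.  The headline quantities (`scripts/acceptance.py`) use 5 seeds per
condition and finish in about a minute; the full CLI study (10 strain
levels × 3 algorithms × 5 seeds) takes tens of minutes.

## Known limitations

* The coarse stage's robustness relies on the continuity-based outlier
  rejection; tissue with genuine displacement discontinuities (slip
  boundaries) would be over-smoothed.
* Lateral displacement is estimated only to whole-line precision and only
  used to re-select the matching post line.
* CNRe on this clean simulator saturates at values far above what physical
  acquisitions reach; between-algorithm folds are the robust statistic.
* The FEM is 2-D plane strain; a physical phantom deforms in 3-D and its
  strain contrast for the same modulus contrast differs.
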