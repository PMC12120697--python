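# Methods

## Droplet model and geometry

A sessile droplet small enough for surface tension to dominate gravity is
modelled as a spherical cap: its side-view silhouette is the segment of a
circle cut by the horizontal substrate line *y = a*. All geometry runs in
a y-up physical frame (mm); images are converted from their y-down pixel
frame via `y_physical = (H − 1 − y_pixel)` and the mm-per-pixel
calibration factor (known length ÷ pixel span, e.g. 10 mm / 1028 px =
0.009728 mm/px).

With the circle centre `(cx, cy)` and radius `r`:

- contact points: `A, B = (cx ∓ √(r² − (a − cy)²), a)`
- base diameter: `D = 2 √(r² − (a − cy)²) = 2 r sin θ`
- contact angle: `θ = arccos((a − cy) / r)` — the branch is fixed so that
  a centre above the baseline gives θ > 90° (hydrophobic substrate), which
  is the regime the silane-coated slides the pipeline targets operate in;
  θ < 90° (centre below the line) is equally supported.
- volume: `V = (π D³ / 24) (2 − 3 cos θ + cos³ θ) / sin³ θ` µL (D in mm).
  This is algebraically identical to the classical cap form
  `V = (π h / 6)(3 (D/2)² + h²)` with `h = (D/2)(1 − cos θ)/sin θ`; the
  test suite checks the identity to 1e−9 relative error across
  D ∈ [0.5, 5] mm × θ ∈ [10°, 170°], and the θ = 90° hemisphere limit
  π D³ / 12 exactly.

The droplet is always the segment *above* the baseline: sessile-drop
physics admits no other reading. Angles are reported to 2 decimals,
lengths and volumes to 4 significant figures in CSV output; internal
computation is double precision throughout.

## Measurement pipeline

1. **Preprocessing** (three extraction views): grayscale luminance;
   Canny edges (Gaussian σ = 1.4, hysteresis thresholds 50/150 on 0–255);
   binary threshold (Otsu by default) with the droplet rendered black.
   The merged analysis image is the pixel-wise maximum of the inverted
   binary view and the edge map overlaid on the grayscale view — this
   reinforces the droplet boundary for the accumulator while keeping
   interior contrast. The thresholds are exposed in
   `PreprocessingConfig`; defaults were chosen for 8-bit images with
   moderate contrast.
2. **Circle detection**: a Hough circle accumulator
   (`skimage.transform.hough_circle`) over radii in [5 %, 60 %] of the
   smaller image dimension proposes candidates. The accumulator runs on a
   2× down-scaled edge map with at most 40 radius bins for speed, and
   with a padded ("full output") vote space because a shallow cap
   (θ well below 90°) has its circle centre *outside* the frame. Each
   candidate is then refined on an integer and finally a half-pixel local
   grid, scored by the mean smoothed gradient magnitude of the gray view
   interpolated along the candidate perimeter; the gradient field is
   symmetric about the true boundary, so the refinement is unbiased by the
   Canny mask's integer rasterisation. Circle parameters are kept at
   half-pixel resolution; no further sub-pixel fitting is done. Ties
   (scores equal at 2 decimals) break toward the larger radius, then the
   topmost centre. An accumulator peak below 0.12 (normalized votes)
   raises `NoCircleFoundError` — a full circle scores near 1, and the
   shortest arc the pipeline must handle (θ = 60°, one third of the
   perimeter) scores ≈ 0.33.
3. **Baseline detection**: among rows below the detected circle's apex,
   the row with the longest horizontal run of edge pixels is selected
   (minimum run: 5 % of the image width — a bulging θ > 90° droplet
   occludes most of the substrate line), then refined to half-pixel
   resolution by a parabolic fit to the column-averaged vertical gradient
   around that row. An explicit override row always wins. The apex (not
   the centre) bounds the search because for θ < 90° the circle centre
   lies below the substrate line.
4. **Measurement**: pixel→mm and y-down→y-up conversion, then the
   geometry above. Stage failures (`NoCircleFoundError`,
   `BaselineNotFoundError`, `NoIntersectionError`) carry the failing
   stage's name; batch processing records them per row and never aborts.

The half-pixel refinement of both circle and baseline matters: volume
scales as r³ and the cut-plane sensitivity is dV/da = −π (D/2)², so at the
default calibration a ±0.5 px bias on either quantity alone moves the
volume of a 1 mm droplet by ~1.5 %.

## Synthetic droplet renderer

`render_droplet` rasterises the exact silhouette (dark cap and substrate
on a light background) with 4× supersampling, then applies Gaussian blur
(σ = 1 px) and seeded additive Gaussian pixel noise (default σ = 5/255,
a mild sensor-noise level). The ground truth is computed analytically by
the geometry module before rasterisation, so pipeline accuracy can be
asserted without annotation. Defaults: 400×480 px frame, baseline at row
340, 0.009728 mm/px — the scale at which a 1–3.5 mm droplet spans
100–360 px, comparable to a goniometer camera. The renderer draws an
ideal axisymmetric cap: no meniscus reflections, satellite droplets,
illumination gradients or lens distortion. Passing the render-and-recover
tests therefore demonstrates correctness of the detection and geometry
chain, not robustness to every artefact of real photographs; the
baseline-override and config hooks exist for exactly those harder images.

## Parameter → volume surrogate

The real dispensing physics behind a parameter→volume dataset is not
published, so the tabular generator uses a smooth power-law surface

V = V₀ (P/P₀)^{a_P} (t/t₀)^{a_t} (d/d₀)^{a_d} (µ/µ₀)^{−a_µ} (1 + a_c (c−c₀)/c₀)

anchored at V₀ = 6.54 µL (the observed medium-droplet mean) for the
reference levels µ₀ = 10.03 mPa·s, d₀ = 0.26 mm, t₀ = 0.1 s, P₀ = 2 psi,
c₀ = 9.33×10⁵ cells/mL. Anchoring at the high pressure level keeps the
surface inside [0.5, 20] µL across the whole design grid (two
viscosities 10.03/24.66 mPa·s; nozzle inner diameters 0.337/0.26/0.21 mm;
times 0.05/0.1/0.15 s; pressures 1.5/2 psi; two cell concentrations,
2.8×10⁶ and 5.6×10⁶ cells per 3 mL batch stored as cells/mL).

The default "empirical" exponents (a_t = 1, a_d = 1.5, a_P = 1,
a_µ = 0.3, a_c = 0.02) order the per-parameter response spans as
time (3×) > nozzle (2.0×) > pressure (1.33×) > viscosity (1.31×) > cells
(1.02×), so forest feature importance on generated data reproduces the
qualitative ranking observed on real droplets (dispensing time first,
then nozzle size, then pressure, with viscosity and cell concentration
minor). A "poiseuille" preset (a_d = 4, Hagen–Poiseuille flow scaling)
is provided as a physically motivated stress test; which of the two
better reflects real dispensing hardware is an open question, hence both
ship. Sampling draws each parameter uniformly from its levels with the
two viscosities exactly balanced (⌊n/2⌋/⌈n/2⌉ — 879/879 at n = 1758),
and multiplies the noiseless volume by (1 + ε), ε ~ N(0, noise_cv) with
noise_cv = 0.02 by default: a 2 % dispense-to-dispense variability, small
enough that an adequate model can reach R² ≈ 0.98 on held-out data, large
enough that overfitting is measurable in the grid-search curves. The
surrogate is smooth and low-dimensional; real datasets will carry
heteroscedastic noise and interactions it does not emulate.

## Regression harness

- **Split**: seeded uniform shuffle, train = ⌊0.7 n⌋ (1230/528 at 1758).
- **Cross-validation**: seeded partition into k = 10 near-equal folds;
  per-fold train/validation MAE, MSE, RMSE, R² plus wall-clock times;
  means and standard deviations over folds.
- **Grid search**: exhaustive, scored by mean validation RMSE (the
  selection criterion was an open choice; RMSE matches the loss the
  neural models optimise). Candidates are visited in the given order and
  only a strictly better score displaces the incumbent, so ties resolve
  toward the simpler model when grids are listed in ascending complexity.
- **Models** (tuned defaults): decision tree (max_depth = 7), random
  forest (n_estimators = 10, squared-error criterion, unlimited depth,
  min_samples_split = 2, min_samples_leaf = 1), polynomial regression
  (degree 7 feature expansion + ordinary least squares), MLP (hidden
  layers 64/32, ReLU, Adam, lr 1e−3, batch 32, 100 epochs), LSTM (one
  recurrent layer of 32 units, Adam, lr 1e−3, batch 32, 100 epochs).
  Trees consume raw features (scale-invariant); polynomial regression,
  MLP and LSTM standardize features, and the two neural models also
  standardize the target, inverting the scaling at predict time —
  without target scaling a 100-epoch budget is spent mostly on learning
  the output magnitude.
- **LSTM framing**: the records carry no real temporal ordering, so each
  is a length-one sequence of the five-feature vector. The implementation
  is a generic textbook LSTM in numpy — per-gate weight matrices,
  recurrent weights, forget-bias 1 initialisation, full backpropagation
  through time — validated against finite-difference gradients in the
  test suite, and it accepts true (n, T, features) sequences as well.
- **Metrics**: MAE, MSE, RMSE = √MSE, R² = 1 − SSres/SStot. R² is not
  clamped: a worse-than-mean predictor reports a negative value. A
  zero-variance target yields R² = NaN with a warning.
- **Importance**: `feature_importances_` of the random forest —
  per-feature impurity (variance) reduction summed over split nodes,
  averaged over trees, normalized to sum to one. A constant target has no
  splits; uniform weights are reported with a warning.
- **Timing**: monotonic wall clock around fit/predict only, in ms.
  Absolute values are hardware-dependent; only orderings are asserted
  (trees < polynomial < MLP < LSTM). `compare_algorithms` performs one
  untimed warm-up fit per algorithm so first-call lazy initialisation
  does not pollute the benchmark, then re-splits and re-seeds per repeat.

## Problem sizes and numerical choices

The test suite exercises the full pipeline on 100 seeded renders
(noiseless and noisy) plus a 30-image three-group fixture, and the
harness on 1758-record datasets — the same scale as the motivating
experiments; benchmark repeats default to 10 in the API and use 3 in the
ordering test, where the inter-algorithm gaps span three orders of
magnitude. Degenerate inputs are defined errors, not silent results:
non-positive calibration lengths, a baseline that misses the circle,
θ ∈ {0°, 180°} (sin³θ = 0), empty images, empty batches, malformed CSV
cells (strict comma/'.' dialect, exact header). Determinism is a tested
contract: every stochastic step (rendering noise, sampling, splits, fold
assignment, weight initialisation, minibatch order) derives from an
explicit integer seed, and repeated runs produce byte-identical CSV
output for the measurement batch and the dataset writer.

## Known limitations

- The cap model ignores gravity flattening (valid below the capillary
  length), non-axisymmetric droplets and contact-angle hysteresis; no
  Young–Laplace profile fitting is attempted.
- One droplet per frame is assumed; multi-droplet segmentation is out of
  scope.
- The surrogate response surface is a stand-in, not a fit to real
  dispensing data; absolute error metrics on it are not comparable to
  those measured on laboratory datasets, which is why model adequacy is
  asserted through R² bounds and orderings rather than absolute MAE.
- Wall-clock orderings are asserted on one CPU; exotic BLAS threading
  configurations could perturb the polynomial-regression timing.
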