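# Methods

This note documents the models, estimators and design choices behind
`suturemetrics`, in the order the pipeline runs.

## Input model and resampling

A suture is an *open* planar curve given as ordered semi-landmarks
`(x_i, y_i)`, `i = 0..n-1`, in arbitrary units; the first and last points
are the suture endpoints, and point order encodes the path (curves are
never re-sorted by x, because complex sutures loop and are multi-valued in
x). All downstream metrics assume a uniform sampling of the curve, so every
curve is first resampled to `resample_n` points (default **500**, a density
at which fine morphological detail of typical digitized sutures survives;
studies using much coarser digitization should confirm the count captures
their finest interdigitation).

Resampling is *equidistant in the Euclidean sense*: consecutive resampled
points are at equal straight-line (chord) distance, with all points lying
on the input polyline (linear interpolation; no spline smoothing, which
would alter complexity scores). The spacing is found by a fixed-point
iteration — place points at equal arc length, measure the resulting chord
lengths, remap stations so cumulative chord length becomes uniform, repeat
to a relative spread below 1e-13 (capped at 100 iterations, best iterate
kept). Endpoints are preserved exactly. On smooth curves the resampled
polyline preserves total arc length to well under 0.5% for n >= 100 (the
tests verify this against the analytic arc length of a sine).

## Superimposition

Generalized Procrustes analysis removes the non-shape components:

1. translate each configuration's centroid to the origin;
2. scale to unit **centroid size** (root summed squared distances to the
   centroid);
3. iteratively rotate each configuration to the evolving consensus (the
   normalized mean shape) until the consensus changes by less than `tol`
   (RMS, default **1e-8**) or `max_iter` (**100**) is reached.
   Non-convergence sets a flag on the result rather than raising.

Only *proper* rotations (determinant +1) are fitted, with the closed-form
2D solution `theta = atan2(h01 - h10, h00 + h11)` for `H = X^T Y`.
Reflections are deliberately not removed: mirror-image sutures ('n' vs 'u'
arches) are distinct morphologies and must remain separable in shape
space. No semi-landmark sliding is performed — curves are aligned as fixed
configurations; sliding (bending-energy or chord-distance) is out of scope.

## Deviation signal

Metrics that need a 1D profile use the *deviation signal*: the curve is
rigidly mapped to the chord frame (first endpoint at the origin, last on
the positive x-axis) and the y-coordinates are read off in station order.
Indexing by arc-length station — not by x-projection — keeps the signal
single-valued for looping sutures. Endpoints are exactly zero by
construction. Because curves are superimposed first, signal amplitudes are
in unit-centroid-size units and comparable across specimens. No detrending
beyond the chord frame is applied; mean removal before the STFT exists as
a config flag (`remove_mean`, default off) since the chord frame already
fixes the endpoints to zero.

Flat-signal guard: a signal whose maximum absolute value is below
`1e-9 x chord length` is treated as exactly flat (alignment arithmetic
leaves ~1e-16 noise on perfectly straight sutures, which would otherwise
be renormalized into spurious structure by scale-invariant estimators).

## The five metrics

**SI** — sum of consecutive inter-landmark distances divided by the
endpoint chord. Invariant to similarity transforms; `SI >= 1` with
equality iff the polyline is straight (ratios within 1e-12 of 1 are
snapped to exactly 1; accumulated float error is O(n·eps) ~ 1e-13, far
below any genuine curvature contribution).

**Lobe detection and SCI** — interdigitation lobes are local extrema of
the deviation signal (both signs), graded by topographic prominence
relative to the maximum absolute deviation A: prominence `>= 0.5 A` is a
*major* lobe, `[0.05 A, 0.5 A)` a *minor* lobe, below that digitization
noise. Prominence is reparameterization-stable, unlike raw peak height;
both fractions are config keys. The complexity factor is
`f(M, m) = 0.2 (1 + M + m/2)`: a zero-lobe baseline of 1/5, one unit of
weight per major lobe, half per minor, strictly increasing in both counts;
`SCI = SI x f`. A straight suture thus scores `SCI = 0.2`.

**FD, box counting** — the signal graph is min–max scaled into the unit
square (the standard normalization for box-counting a series; without it
the thin post-Procrustes amplitude band collapses every profile to
dimension 1). Occupied boxes are counted per column from a dense
piecewise-linear evaluation of the graph (so boxes crossed between
stations count), over a dyadic ladder starting at the unit square and
halving up to `fd_box_octaves` (**8**) times, stopping once boxes are
narrower than two stations; the dimension is the negated OLS slope of
`log2 N(s)` on `log2 s` over all usable scales (no scale-window pruning;
at least three scales required). Estimates are clamped to [1, 2] with the
raw slope retained.

**FD, madogram** — `gamma1(t) = mean_u |X(u+t) - X(u)|` for lags
`t = 1..max_lag`; OLS of `log gamma1` on `log t` gives the Hurst exponent
H and `D = 2 - H`, clamped to [1, 2] with the raw value retained.
`max_lag` defaults to **n/128** (4 lags at n = 500, minimum 2). The
small-lag choice matters: increment-scaling estimators are consistent only
in the small-lag regime, and lags spanning whole interdigitation periods
fold the periodic structure into the fit and push D toward 2 for perfectly
regular fast waves. On exact fractional Brownian motion (n = 1024, 100
seeds per H in {0.2, 0.5, 0.8}) the acceptance script measures the mean
absolute error of the recovered dimension at roughly 0.02 with this
default. A constant signal has no defined slope and reports D = 1 with a
`degenerate` flag.

**STFT and PSD** — the signal is cut into contiguous segments of
`stft_window` samples (default **50**, n/10) every `stft_hop` samples
(default **25**, half-window overlap), each multiplied by the taper
(default **Hamming**; any scipy window name) and transformed with a real
DFT; harmonics 0..window/2 are kept per window, with no padding or
centering (`windows = floor((n - W)/hop) + 1`). The PSD score averages
squared coefficient magnitudes across windows at each harmonic and sums
the averages over harmonics. The default reporting scale is the raw sum
(which scales with squared signal amplitude — hence the unit-centroid-size
convention); `psd_normalization: log10` reports `log10(1 + raw)` when a
bounded reporting scale is preferred. The normalization in force is
recorded in every run manifest.

## Comparative statistics

*Shape PCA* runs on flattened superimposed coordinates
`(x1, y1, ..., xn, yn)`, centered but **not** standardized — coordinates
share units, and standardizing would distort shape space. *Complexity
-score PCA* defaults to **standardized** variables, because the five
metrics live on incommensurable scales (SI in units of 1–10, SCI in tens,
FDs in [1, 2]); the flag is exposed since either convention is defensible.
Both use the SVD of the (scaled) centered matrix, equivalent to an
eigendecomposition of the covariance/correlation matrix; PCs are ordered
by decreasing variance and signed so each loading vector's
largest-magnitude entry is positive (eigenvector signs are otherwise
arbitrary; correlations against PC scores are therefore defined up to a
global per-PC sign). Contributions are squared loadings x 100 (summing to
100 per PC).

Pearson correlations come with two-sided p-values from the t-transform
`t = r sqrt((n-2)/(1-r^2))` and 95% confidence intervals from the Fisher
z-transform (via `scipy.stats.pearsonr`); no multiple-testing correction
is applied, matching common practice for descriptive correlation plots.
Zero-variance columns yield NaN for their pairs instead of failing the
report. Metric-vs-shape alignment correlates each metric against the PC
scores of every shape PC whose variance fraction exceeds `top_fraction`
(default **0.05**), and requires identical specimen ordering. Heatmap
binning uses k equal-width bins (default **10**) spanning [min, max], the
maximum landing in bin k and constant vectors in bin 1.

## Synthetic sutures

`generate_suture` builds an open curve from (0,0) to (1,0):

- base wave `A sin(2 pi f t)` — `amplitude` A is the interdigitation
  depth relative to the chord, `frequency` f the cycle count;
- `irregularity` sigma adds per-cycle amplitude jitter
  (`1 + sigma N(0,1)`, floored at 0.1) and phase jitter
  (`(pi/2) sigma N(0,1)`), linearly interpolated between cycle centers,
  **plus** a fine-scale fractional-Brownian roughness component
  (H = 0.25, scaled to `0.5 sigma A` standard deviation). The roughness
  term is what distinguishes "irregular" from merely "deformed": real
  irregular sutures carry non-periodic detail at many scales, and without
  it the increment-scaling estimators cannot tell an irregular suture
  from a regular wave;
- `loopiness` lambda shears the wave by its own height,
  `x = t - (2 lambda / (A 2 pi f)) y(t)`. A sheared function graph can
  never self-intersect (coincident points would need equal y *and* equal
  t), yet folds past vertical wherever the local slope satisfies
  `s |dy/dt| > 1`, i.e. for lambda > 0.5 — giving hooked, x-multi-valued
  lobes while guaranteeing a simple path. A brute-force
  segment-intersection check still validates every generated curve.

`generate_spectrum` draws five labelled classes per seed (parameter ranges
in `SPECTRUM_CLASSES`): straight (A = 0); low-amplitude (A 0.02–0.04,
f 4–8); high-frequency (A 0.07–0.10, f 16–24) — many prominent lobes, the
SI/SCI-dominant morphology; high-amplitude-irregular (A 0.13–0.18, f 5–8,
sigma 0.25–0.4) and looping (same depth, lambda 0.65–0.8) — the
roughness/energy-dominant morphologies. The ranges were chosen once so
each class embodies its name at realistic suture proportions (depths up to
~a fifth of the chord, as seen across mammal sutures) and held fixed.

What the generator does **not** emulate: digitization noise and parallax,
anatomical growth processes, spatial non-stationarity along a real suture
(e.g. one straight half and one interdigitated half), and 3D structure.
Passing tests on synthetic spectra therefore demonstrate estimator
correctness and the qualitative metric-divergence structure, not field
performance on any particular empirical dataset.

`generate_fbm` synthesizes exact fractional Gaussian noise by Davies–Harte
circulant embedding (eigenvalues of the embedded covariance clipped at
zero against rounding), cumulates it to fractional Brownian motion and
subtracts the linear bridge so both endpoints are zero — making the path a
valid deviation signal. The bridge slightly perturbs large-lag increments,
one more reason the madogram default fits small lags only.

## Pipeline and reproducibility

`run_pipeline` is a pure function of (input bytes, config): the manifest
records the config, package version and input SHA-256 so deterministic
outputs (every CSV) are byte-reproducible. A degenerate specimen (e.g.
coincident endpoints) is logged to `errors.csv` and skipped; the run
continues with the remaining curves — a single bad outline must not abort
a dataset-scale run.

The acceptance script (`scripts/acceptance.py`) runs the pipeline on an
80-suture spectrum (16 per class) — a dataset-scale problem comparable to
published suture samples — plus 300 fBm recovery paths, a level-4 Koch
profile resampled to 512 stations, and a 20-seed PSD class-separation
experiment; all sizes were chosen as the smallest that make the reported
quantities stable across seeds.

## Known limitations

- Metrics operate on 2D outlines only; 3D suture surfaces are out of scope.
- SCI's lobe counts depend on the two prominence thresholds; the defaults
  (0.5 / 0.05 of max amplitude) are reasonable for clean outlines but are
  configuration, not ground truth.
- Box counting at 500 stations supports only ~7 dyadic scales, so its
  estimates are coarse-scale apparent dimensions rather than asymptotic
  ones; this mirrors how the estimator behaves on any finitely sampled
  natural curve.
- The raw PSD score is amplitude-squared sensitive by design; comparing
  PSD across datasets requires the same superimposition convention.
- GPA assumes one-to-one station correspondence across specimens, which
  equidistant resampling only approximates for strongly unequal suture
  lengths.
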