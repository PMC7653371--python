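# suturemetrics

Quantitative analysis of **cranial suture complexity** from two-dimensional
open-curve outlines.

Cranial sutures — the fibrous joints between skull bones — range from
straight seams to deeply interdigitated, irregular and even looping traces.
Their waviness carries biological signal (growth, biomechanical stress,
diet, development), but sutures lack discrete homologous landmarks, so
their shape is captured as ordered *semi-landmarks* along the open curve
and reduced to univariate **complexity scores** for comparison across
specimens, taxa and ages.

`suturemetrics` implements that workflow end to end, for morphologists who
have digitized suture outlines and want comparable complexity scores:

1. **I/O and resampling** — read TPS or CSV semi-landmark files and
   resample every curve to *n* equidistant points (default 500).
2. **Generalized Procrustes analysis** — remove translation, size
   (unit centroid size) and orientation; proper rotations only, so mirror
   ('n' vs 'u') forms remain distinct.
3. **Deviation signal** — the signed perpendicular offset of each
   semi-landmark from the endpoint chord, indexed by arc-length station
   (well-defined even for looping curves that are multi-valued in x).
4. **Five complexity metrics** per suture:
   - **SI** (sinuosity index): path length / chord length, `SI >= 1`;
   - **SCI** (suture complexity index): `SCI = SI x f(M, m)` with
     `f(M, m) = 0.2 (1 + M + m/2)` over major/minor interdigitation-lobe
     counts detected by topographic prominence;
   - **FD (box counting)**: slope of `log2 N(s)` vs `log2 s` for the
     signal graph on a dyadic box ladder;
   - **FD (madogram)**: `D = 2 - H` with the Hurst exponent `H` fitted to
     the first-order increment scaling
     `gamma1(t) = mean |X(u+t) - X(u)| ~ t^H` at small lags;
   - **PSD**: windowed short-time Fourier transform, squared coefficients
     averaged over windows at each harmonic and summed over harmonics.
5. **Comparative statistics** — shape PCA and complexity-score PCA with
   loadings/contributions, Pearson correlation matrices with p-values and
   Fisher-z confidence intervals, equal-width score binning for heatmaps.

A seeded synthetic-suture generator (`generate_spectrum`) spans the
morphological range — straight, low-amplitude, high-frequency,
high-amplitude-irregular and looping — and exact fractional Brownian
motion (`generate_fbm`) provides ground truth for the fractal estimators,
so the entire pipeline is testable without any digitized specimen.

## Worked example

```python
import suturemetrics as sm

curve = sm.generate_suture(
    sm.SutureParams(amplitude=0.12, frequency=8, irregularity=0.2, seed=4),
    specimen_id="demo",
)
aligned = curve.with_coords(sm.center_and_scale(curve.coords))
rec = sm.compute_all(aligned)
print(f"SI      = {rec.si:.3f}")
print(f"SCI     = {rec.sci:.3f}  (major lobes: {rec.major_lobes}, minor: {rec.minor_lobes})")
print(f"FD box  = {rec.fd_box:.3f}")
print(f"FD mad  = {rec.fd_mad:.3f}  (Hurst H = {rec.hurst:.3f})")
print(f"PSD     = {rec.psd:.4f}")
```

prints

```
SI      = 4.272
SCI     = 14.524  (major lobes: 16, minor: 0)
FD box  = 1.421
FD mad  = 1.039  (Hurst H = 0.961)
PSD     = 0.1123
```

This 8-cycle wave of amplitude 0.12 travels 4.27x its chord (SI). Its 16
prominent crests/troughs give a lobe factor of 3.4, hence SCI 14.5. Box
counting sees moderate space filling at coarse scales (1.42); the madogram,
fitted at station-scale lags, sees a fairly smooth profile (D near 1, H near
1); the PSD score summarizes the spectral power of the deviation signal on
the unit-centroid-size scale.

The same thing from the shell, on a whole dataset:

```sh
suturemetrics synth --out curves.csv --n-per-class 3 --seed 1
suturemetrics run --input curves.csv --dialect csv --out results/
```

`results/` then holds `scores.csv` (one row of all five metrics per
suture), `shape_pca/` and `complexity_pca/` (scores, loadings, variance
fractions, contributions), `correlations.csv` (metric-vs-metric r/p/CI),
`metric_shape_correlations.csv` (metrics vs dominant shape PCs),
`bins.csv` (10 equal-width bins per metric for heatmaps) and
`manifest.yaml` (config, package version, input checksum).

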