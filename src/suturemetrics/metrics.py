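"""The five suture-complexity metrics.

Given an open suture outline resampled to uniform semi-landmarks (and,
for cross-specimen comparability, Procrustes-superimposed), this module
computes:

* **SI** — sinuosity index: total path length / endpoint chord length.
  Dimensionless, >= 1, equal to 1 only for a straight suture.
* **SCI** — suture complexity index: SI times a complexity factor that
  grows with the number of major and minor interdigitation lobes.
* **FD (box counting)** — fractal dimension of the deviation-signal graph
  from occupied-box scaling over a dyadic ladder of box sizes.
* **FD (madogram)** — fractal dimension from first-order increment scaling:
  the madogram gamma1(t) = mean |X(u+t) - X(u)| behaves like t**H for a
  self-affine profile, and D = 2 - H.
* **PSD** — windowed short-time Fourier transform power score: squared STFT
  coefficients averaged over windows at each harmonic, then summed across
  harmonics.

SI, and both FD estimates are invariant to similarity transforms of the
curve; SCI inherits SI's invariances; the raw PSD score scales with squared
signal amplitude, which is why signals are computed on unit-centroid-size
(superimposed) curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.signal import find_peaks, get_window

from .io import LandmarkCurve
from .signals import DegenerateChordError, DeviationSignal, deviation_signal

__all__ = [
    "MetricConfig",
    "ComplexityScores",
    "FractalDimension",
    "StftMatrix",
    "EstimationError",
    "sinuosity_index",
    "detect_lobes",
    "complexity_factor",
    "suture_complexity_index",
    "fd_boxcount",
    "fd_madogram",
    "stft",
    "psd_score",
    "compute_all",
]


class EstimationError(RuntimeError):
    """A scaling fit has too few usable scales."""


@dataclass(frozen=True)
class MetricConfig:
    """Tunable parameters of the five metrics.

    Attributes
    ----------
    resample_n
        Semi-landmarks per suture after resampling (default 500).
    stft_window, stft_hop, stft_taper
        STFT segment length in samples, hop between segments, and taper
        name (any :func:`scipy.signal.get_window` name, e.g. ``hamming``
        or ``boxcar``).  Defaults: n/10 window with half-window hop.
    psd_normalization
        ``"raw"`` reports the plain harmonic sum; ``"log10"`` reports
        ``log10(1 + raw)``, a monotone compression onto a bounded scale.
    lobes_major_frac, lobes_minor_frac
        Prominence thresholds for major/minor interdigitation lobes, as
        fractions of the maximum absolute deviation.
    fd_box_octaves
        Maximum number of dyadic halvings of the bounding square.
    fd_max_lag_frac
        Madogram maximum lag as a fraction of the signal length.  The
        default n/128 (~4 stations at n = 500) keeps the fit inside the
        small-lag scaling regime, where increment scaling estimators are
        least biased; large lags mix in the periodic structure of
        interdigitation and bias the dimension upward.
    remove_mean
        Subtract the signal mean before the STFT (off by default: the
        chord frame already removes the linear trend).
    """

    resample_n: int = 500
    stft_window: int = 50
    stft_hop: int = 25
    stft_taper: str = "hamming"
    psd_normalization: str = "raw"
    lobes_major_frac: float = 0.5
    lobes_minor_frac: float = 0.05
    fd_box_octaves: int = 8
    fd_max_lag_frac: float = 1.0 / 128.0
    remove_mean: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricConfig":
        return cls(**{k: v for k, v in d.items()})


@dataclass(frozen=True)
class FractalDimension:
    """A fractal-dimension estimate with its raw (unclamped) value.

    ``estimate`` is clipped to the theoretical range [1, 2] for a planar
    curve graph; ``raw`` keeps the fitted value so estimator noise outside
    the range stays visible.  ``hurst`` is the fitted Hurst exponent for
    increment-scaling estimators (None for box counting).
    """

    estimate: float
    raw: float
    n_scales: int
    hurst: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class StftMatrix:
    """Short-time Fourier transform of a deviation signal.

    ``coefficients[w, k]`` is the complex amplitude of harmonic ``k``
    (0..window_length//2) in window ``w``.  Windows tile the signal with
    no padding: ``windows == (n - window_length) // hop + 1``.
    """

    coefficients: np.ndarray = field(repr=False)
    window_length: int
    hop: int
    taper: str

    @property
    def windows(self) -> int:
        return self.coefficients.shape[0]

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.coefficients.shape[1])


@dataclass(frozen=True)
class ComplexityScores:
    """Per-suture record of the five metric values and their intermediates."""

    specimen_id: str
    si: float
    sci: float
    fd_box: float
    fd_mad: float
    psd: float
    major_lobes: int
    minor_lobes: int
    hurst: float
    fd_box_raw: float
    fd_mad_raw: float

    METRIC_COLUMNS = ("si", "sci", "fd_box", "fd_mad", "psd")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# SI and SCI
# ---------------------------------------------------------------------------

def sinuosity_index(coords: np.ndarray) -> float:
    """Path length over chord length of an open polyline; >= 1 always.

    Raises
    ------
    DegenerateChordError
        If the endpoints coincide.
    """
    coords = np.asarray(coords, dtype=float)
    chord = float(np.linalg.norm(coords[-1] - coords[0]))
    if chord == 0.0:
        raise DegenerateChordError("endpoints coincide; SI undefined")
    path = float(np.linalg.norm(np.diff(coords, axis=0), axis=1).sum())
    ratio = path / chord
    # path >= chord with equality iff collinear; summation rounding is
    # O(n*eps) ~ 1e-13, far below any genuine curvature contribution
    return 1.0 if ratio - 1.0 < 1e-12 else ratio


def detect_lobes(
    signal: DeviationSignal,
    major_frac: float = 0.5,
    minor_frac: float = 0.05,
) -> tuple[int, int]:
    """Count major and minor interdigitation lobes of a deviation signal.

    A lobe is a local extremum (either sign).  Its size is measured by
    topographic prominence; relative to the maximum absolute deviation A,
    prominence >= ``major_frac * A`` makes a major lobe, prominence in
    ``[minor_frac * A, major_frac * A)`` a minor lobe, and anything smaller
    is treated as digitization noise.
    """
    if not 0 < minor_frac < major_frac <= 1:
        raise ValueError("need 0 < minor_frac < major_frac <= 1")
    v = signal.values
    amp = float(np.abs(v).max())
    if amp <= 1e-9 * signal.chord_length:
        return (0, 0)  # flat to within numerical noise of the alignment
    floor = minor_frac * amp
    cut = major_frac * amp
    major = minor = 0
    for sig in (v, -v):
        _, props = find_peaks(sig, prominence=floor)
        prom = props["prominences"]
        major += int((prom >= cut).sum())
        minor += int((prom < cut).sum())
    return major, minor


def complexity_factor(major_lobes: int, minor_lobes: int) -> float:
    """Lobe-based multiplier turning SI into SCI.

    ``factor = 0.2 * (1 + major + minor/2)``: the zero-lobe baseline is
    1/5, each major lobe contributes a full unit of weight and each minor
    lobe half a unit, so the factor is strictly increasing in both counts.
    """
    if major_lobes < 0 or minor_lobes < 0:
        raise ValueError("lobe counts must be non-negative")
    return 0.2 * (1.0 + major_lobes + 0.5 * minor_lobes)


def suture_complexity_index(si: float, factor: float) -> float:
    """SCI = SI x complexity factor."""
    if si < 1.0:
        raise ValueError(f"SI must be >= 1, got {si}")
    return si * factor


# ---------------------------------------------------------------------------
# Fractal dimensions
# ---------------------------------------------------------------------------

def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    return float((x @ (y - y.mean())) / (x @ x))


def fd_boxcount(signal: DeviationSignal, octaves: int = 8) -> FractalDimension:
    """Box-counting dimension of the deviation-signal graph.

    The graph is embedded in the unit square (stations mapped to [0, 1] on
    x, values min-max scaled on y, the standard normalization for
    box-counting a series); occupied boxes N(s) are counted on a dyadic
    ladder of box sizes s (one halving per octave, stopping once boxes are
    narrower than two stations), and the dimension is the negated OLS slope
    of log2 N on log2 s.

    Raises
    ------
    EstimationError
        If fewer than 3 usable scales remain.
    """
    v = signal.values
    n = v.size
    if n < 64:
        raise EstimationError(f"need >= 64 stations, got {n}")
    x = np.linspace(0.0, 1.0, n)
    vrange = float(v.max() - v.min())
    if vrange <= 1e-9 * signal.chord_length:
        v = np.zeros(n)  # flat to within numerical noise of the alignment
    else:
        v = (v - v.min()) / vrange  # unit-square embedding
    side = 1.0

    # dense piecewise-linear samples of the graph so boxes crossed between
    # stations are counted as occupied
    xf = np.linspace(0.0, 1.0, max(4096, 4 * n))
    yf = np.interp(xf, x, v)

    sizes, counts = [], []
    for j in range(1, octaves + 1):
        s = side / 2.0**j
        if s < 2.0 / (n - 1):  # boxes narrower than two stations
            break
        ncols = int(np.ceil(1.0 / s))
        col = np.minimum((xf / s).astype(int), ncols - 1)
        ymin = np.full(ncols, np.inf)
        ymax = np.full(ncols, -np.inf)
        np.minimum.at(ymin, col, yf)
        np.maximum.at(ymax, col, yf)
        occupied = np.isfinite(ymin)
        boxes = (
            np.floor(ymax[occupied] / s) - np.floor(ymin[occupied] / s) + 1
        ).sum()
        sizes.append(s)
        counts.append(boxes)
    if len(sizes) < 3:
        raise EstimationError(f"only {len(sizes)} usable scales")
    slope = _ols_slope(np.log2(sizes), np.log2(counts))
    raw = -slope
    return FractalDimension(
        estimate=float(np.clip(raw, 1.0, 2.0)), raw=raw, n_scales=len(sizes)
    )


def fd_madogram(signal: DeviationSignal, max_lag: int | None = None) -> FractalDimension:
    """Madogram (first-order variogram) fractal dimension, D = 2 - H.

    gamma1(t) = mean_u |X(u+t) - X(u)| is computed for lags t = 1..max_lag
    and log gamma1 is regressed on log t; the slope estimates the Hurst
    exponent H, and the dimension is D = 2 - H, clamped to [1, 2].

    A constant signal has an undefined slope; it is reported as D = 1 with
    ``degenerate=True``.
    """
    v = signal.values
    n = v.size
    if n < 64:
        raise EstimationError(f"need >= 64 stations, got {n}")
    if max_lag is None:
        max_lag = max(2, n // 128)
    if not 2 <= max_lag <= n // 4:
        raise ValueError(f"max_lag must be in [2, n/4], got {max_lag}")
    if np.abs(v).max() <= 1e-9 * signal.chord_length:
        # flat to within numerical noise of the alignment
        return FractalDimension(
            estimate=1.0, raw=1.0, n_scales=max_lag, hurst=1.0, degenerate=True
        )
    lags = np.arange(1, max_lag + 1)
    gamma = np.array([np.abs(v[t:] - v[:-t]).mean() for t in lags])
    if np.any(gamma == 0.0):
        return FractalDimension(
            estimate=1.0, raw=1.0, n_scales=len(lags), hurst=1.0, degenerate=True
        )
    hurst = _ols_slope(np.log(lags), np.log(gamma))
    raw = 2.0 - hurst
    return FractalDimension(
        estimate=float(np.clip(raw, 1.0, 2.0)),
        raw=raw,
        n_scales=len(lags),
        hurst=hurst,
    )


# ---------------------------------------------------------------------------
# STFT and PSD
# ---------------------------------------------------------------------------

def stft(
    signal: DeviationSignal,
    window_length: int = 50,
    hop: int = 25,
    taper: str = "hamming",
) -> StftMatrix:
    """Short-time Fourier transform with contiguous, unpadded windows.

    Each length-``window_length`` segment (start positions 0, hop, 2*hop,
    ...) is multiplied by the taper and transformed with a real DFT; the
    coefficients for harmonics 0..window_length//2 are returned per window.
    """
    v = signal.values
    n = v.size
    if window_length > n:
        raise ValueError(f"window_length {window_length} exceeds signal length {n}")
    if hop < 1:
        raise ValueError("hop must be >= 1")
    w = get_window(taper, window_length, fftbins=True)
    n_windows = (n - window_length) // hop + 1
    starts = np.arange(n_windows) * hop
    segments = np.stack([v[s : s + window_length] for s in starts])
    coeffs = np.fft.rfft(segments * w, axis=1)
    return StftMatrix(
        coefficients=coeffs, window_length=window_length, hop=hop, taper=taper
    )


def psd_score(m: StftMatrix, normalization: str = "raw") -> float:
    """Power-spectrum score of an STFT.

    Squared coefficient magnitudes are averaged across windows at each
    harmonic, and the averages are summed over harmonics.  With
    ``normalization="log10"`` the sum is reported as ``log10(1 + raw)``.
    """
    power = (np.abs(m.coefficients) ** 2).mean(axis=0)  # average per harmonic
    raw = float(power.sum())
    if normalization == "raw":
        return raw
    if normalization == "log10":
        return float(math.log10(1.0 + raw))
    raise ValueError(f"unknown psd normalization {normalization!r}")


# ---------------------------------------------------------------------------
# Full per-suture record
# ---------------------------------------------------------------------------

def compute_all(curve: LandmarkCurve, cfg: MetricConfig | None = None) -> ComplexityScores:
    """Compute all five metrics for one (resampled, superimposed) curve.

    Deterministic for a fixed configuration; metric-level errors are
    re-raised with the specimen id prepended.
    """
    cfg = cfg or MetricConfig()
    try:
        si = sinuosity_index(curve.coords)
        sig = deviation_signal(curve.coords)
        major, minor = detect_lobes(sig, cfg.lobes_major_frac, cfg.lobes_minor_frac)
        sci = suture_complexity_index(si, complexity_factor(major, minor))
        box = fd_boxcount(sig, octaves=cfg.fd_box_octaves)
        mad = fd_madogram(sig, max_lag=max(2, int(sig.n_stations * cfg.fd_max_lag_frac)))
        values = sig
        if cfg.remove_mean:
            values = replace(sig, values=sig.values - sig.values.mean())
        mat = stft(values, cfg.stft_window, cfg.stft_hop, cfg.stft_taper)
        psd = psd_score(mat, cfg.psd_normalization)
    except (DegenerateChordError, EstimationError, ValueError) as exc:
        raise type(exc)(f"{curve.specimen_id}: {exc}") from exc
    return ComplexityScores(
        specimen_id=curve.specimen_id,
        si=si,
        sci=sci,
        fd_box=box.estimate,
        fd_mad=mad.estimate,
        psd=psd,
        major_lobes=major,
        minor_lobes=minor,
        hurst=float(mad.hurst),
        fd_box_raw=box.raw,
        fd_mad_raw=mad.raw,
    )
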