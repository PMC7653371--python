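"""Synthetic suture outlines and fractal test signals.

Real cranial sutures range from straight lines through regularly
interdigitated waves to irregular, deeply folded traces whose crests
overhang (multi-valued in x).  This module generates parametrized open
curves spanning that spectrum, plus exact fractional Brownian motion
paths used as ground truth for the fractal-dimension estimators, so the
whole pipeline is testable without any digitized specimen.

The base waveform is ``amplitude * sin(2*pi*frequency*t)`` on the unit
chord, with optional per-cycle amplitude/phase jitter (``irregularity``)
and a parametric shear (``loopiness``) that makes lobes overhang while
keeping the path simple: ``x = t - s*y(t)`` with
``s = 2*loopiness/(amplitude*omega)``.  A sheared function graph can never
self-intersect (two coincident points would need equal y *and* equal t),
yet folds past vertical wherever ``s*|dy/dt| > 1`` — i.e. once loopiness
exceeds 0.5 — so crests and troughs lean into hooked, x-multi-valued
interdigitations.  A brute-force segment-intersection check still guards
every generated curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LandmarkCurve, resample_equidistant
from .signals import DeviationSignal

__all__ = [
    "SutureParams",
    "SPECTRUM_CLASSES",
    "generate_suture",
    "generate_spectrum",
    "generate_fbm",
    "koch_profile",
]


@dataclass(frozen=True)
class SutureParams:
    """Parameters of one synthetic suture.

    Attributes
    ----------
    n_points
        Equidistant semi-landmarks in the output curve.
    amplitude
        Interdigitation depth relative to the unit chord.
    frequency
        Interdigitation cycles along the chord.
    irregularity
        Roughness of the wave: standard deviation of per-cycle
        amplitude/phase jitter, plus the relative magnitude of a
        fine-scale fractional-Brownian roughness component (irregular
        sutures carry non-periodic detail at many scales, not just a
        deformed fundamental).  0 gives a perfectly regular wave.
    loopiness
        In [0, 1): 0 is a plain wave; above 0.5 crests fold past vertical
        and the outline becomes multi-valued in x.
    seed
        Seed for the jitter; identical (params, seed) gives identical
        coordinates.
    """

    n_points: int = 500
    amplitude: float = 0.05
    frequency: float = 8.0
    irregularity: float = 0.0
    loopiness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.frequency < 0:
            raise ValueError("amplitude and frequency must be >= 0")
        if not 0 <= self.loopiness < 1:
            raise ValueError("loopiness must be in [0, 1)")
        if self.irregularity < 0:
            raise ValueError("irregularity must be >= 0")


def _self_intersects(coords: np.ndarray) -> bool:
    """Brute-force proper-crossing test between non-adjacent segments."""
    p = coords[:-1]
    q = coords[1:]
    d = q - p
    n = p.shape[0]
    idx = np.arange(n)
    for i in range(n - 2):
        j = idx[i + 2 :]
        # orientation tests for segment i against segments j
        r = d[i]
        s = d[j]
        pq = p[j] - p[i]
        rxs = r[0] * s[:, 1] - r[1] * s[:, 0]
        qpxr = pq[:, 0] * r[1] - pq[:, 1] * r[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            # p_i + t r = p_j + u s  =>  t = pq x s / (r x s), u = pq x r / (r x s)
            t = (pq[:, 0] * s[:, 1] - pq[:, 1] * s[:, 0]) / rxs
            u = qpxr / rxs
        hit = (rxs != 0) & (t > 1e-12) & (t < 1 - 1e-12) & (u > 1e-12) & (u < 1 - 1e-12)
        if hit.any():
            return True
    return False


def generate_suture(p: SutureParams, specimen_id: str = "synthetic") -> LandmarkCurve:
    """Generate one open synthetic suture from (0, 0) to (1, 0).

    Raises
    ------
    ValueError
        If the parameter combination produces a self-intersecting path
        (reduce ``loopiness`` or ``irregularity``).
    """
    rng = np.random.default_rng(p.seed)
    dense = 4096
    while dense < 8 * p.n_points:
        dense *= 2
    t = np.linspace(0.0, 1.0, dense)

    if p.amplitude == 0.0 or p.frequency == 0.0:
        y = np.zeros(dense)
        x = t
    else:
        omega = 2.0 * np.pi * p.frequency
        n_cycles = max(1, int(np.ceil(p.frequency)))
        if p.irregularity > 0:
            amp_mult = np.clip(1.0 + p.irregularity * rng.standard_normal(n_cycles), 0.1, None)
            phase = 0.5 * np.pi * p.irregularity * rng.standard_normal(n_cycles)
            centers = (np.arange(n_cycles) + 0.5) / p.frequency
            a_t = np.interp(t, centers, amp_mult)
            ph_t = np.interp(t, centers, phase)
        else:
            a_t = np.ones(dense)
            ph_t = np.zeros(dense)
        y = p.amplitude * a_t * np.sin(omega * t + ph_t)
        if p.irregularity > 0:
            # fine-scale multi-octave roughness (endpoints already zero);
            # H = 0.25 keeps station-scale increments visible to the
            # madogram the way digitized natural detail is
            rough = generate_fbm(0.25, dense, seed=int(rng.integers(0, 2**31 - 1)))
            y = y + 0.5 * p.irregularity * p.amplitude * rough.values / rough.values.std()
        y = y - (y[0] + t * (y[-1] - y[0]))  # pin endpoints onto the chord
        # shear by the wave's own height; folds appear once loopiness > 0.5
        shear = 2.0 * p.loopiness / (p.amplitude * omega)
        x = t - shear * y

    coords = np.column_stack([x, y])

    curve = resample_equidistant(LandmarkCurve(specimen_id, coords), p.n_points)
    if _self_intersects(curve.coords):
        raise ValueError(
            f"self-intersecting suture for {p}; reduce loopiness/irregularity"
        )
    return curve


#: The five morphological classes spanned by the generator, from straight
#: to looping.  Ranges are (low, high) for per-curve uniform draws.
SPECTRUM_CLASSES: dict[str, dict] = {
    "straight": dict(amplitude=(0.0, 0.0), frequency=(0.0, 0.0), irregularity=0.0, loopiness=0.0),
    "low_amplitude": dict(amplitude=(0.02, 0.04), frequency=(4.0, 8.0), irregularity=0.05, loopiness=0.0),
    "high_frequency": dict(amplitude=(0.07, 0.10), frequency=(16.0, 24.0), irregularity=0.05, loopiness=0.0),
    "high_amplitude_irregular": dict(amplitude=(0.13, 0.18), frequency=(5.0, 8.0), irregularity=(0.25, 0.4), loopiness=0.0),
    "looping": dict(amplitude=(0.13, 0.18), frequency=(5.0, 8.0), irregularity=(0.1, 0.2), loopiness=(0.65, 0.8)),
}


def generate_spectrum(
    n_per_class: int, seed: int = 0, n_points: int = 500
) -> tuple[list[LandmarkCurve], list[str]]:
    """Generate a labelled set of curves covering the morphological spectrum.

    Five classes (see :data:`SPECTRUM_CLASSES`): straight, low-amplitude,
    high-frequency, high-amplitude-irregular and looping sutures.
    Deterministic for a fixed ``seed``.

    Returns
    -------
    (curves, labels)
        ``5 * n_per_class`` curves with their class labels, in class order.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    curves: list[LandmarkCurve] = []
    labels: list[str] = []
    for label, spec in SPECTRUM_CLASSES.items():
        for i in range(n_per_class):
            draw = lambda v: float(rng.uniform(*v)) if isinstance(v, tuple) else float(v)
            params = SutureParams(
                n_points=n_points,
                amplitude=draw(spec["amplitude"]),
                frequency=round(draw(spec["frequency"])) if spec["frequency"] != (0.0, 0.0) else 0.0,
                irregularity=draw(spec["irregularity"]),
                loopiness=draw(spec["loopiness"]),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            curve = None
            last_exc: ValueError | None = None
            for _attempt in range(5):
                try:
                    curve = generate_suture(params, specimen_id=f"{label}_{i:02d}")
                    break
                except ValueError as exc:
                    # rare jitter-induced self-intersection: soften and retry
                    last_exc = exc
                    params = SutureParams(
                        n_points=params.n_points,
                        amplitude=params.amplitude,
                        frequency=params.frequency,
                        irregularity=params.irregularity * 0.5,
                        loopiness=params.loopiness * 0.9,
                        seed=params.seed + 1,
                    )
            if curve is None:
                raise last_exc
            curves.append(curve)
            labels.append(label)
    return curves, labels


def generate_fbm(H: float, n: int, seed: int = 0) -> DeviationSignal:
    """Exact fractional Brownian motion path, bridged to zero endpoints.

    Fractional Gaussian noise is synthesized by circulant embedding
    (Davies–Harte) of the fGn autocovariance
    ``r(k) = 0.5 * (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})`` and cumulated
    into an fBm path of ``n`` stations; a linear bridge correction pins
    both endpoints to 0 so the path is a valid deviation signal.

    ``n`` must be a power of two; ``H`` in (0, 1).
    """
    if not 0 < H < 1:
        raise ValueError(f"H must be in (0, 1), got {H}")
    if n < 4 or (n & (n - 1)) != 0:
        raise ValueError(f"n must be a power of two >= 4, got {n}")
    rng = np.random.default_rng(seed)
    m = 2 * n
    k = np.arange(n + 1, dtype=float)
    r = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
    c = np.concatenate([r, r[-2:0:-1]])  # circulant first row, length 2n
    lam = np.fft.fft(c).real
    lam = np.clip(lam, 0.0, None)  # guard tiny negative rounding
    g = rng.standard_normal(m)
    fgn = np.fft.ifft(np.sqrt(lam) * np.fft.fft(g)).real[: n - 1]
    path = np.concatenate([[0.0], np.cumsum(fgn)])
    t = np.arange(n) / (n - 1)
    path = path - t * path[-1]  # bridge: end pinned to 0
    return DeviationSignal(values=path, chord_length=1.0)


def koch_profile(levels: int = 4) -> LandmarkCurve:
    """Triadic Koch curve from (0, 0) to (1, 0) as an open polyline.

    Each refinement replaces every segment by four segments of a third the
    length with a 60-degree bump; ``levels`` refinements give ``4**levels``
    segments.  The limiting curve has dimension log 4 / log 3.
    """
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    rot60 = np.array([[0.5, np.sqrt(3) / 2], [-np.sqrt(3) / 2, 0.5]])
    for _ in range(levels):
        new = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            d = (b - a) / 3.0
            p1 = a + d
            p2 = p1 + d @ rot60
            p3 = a + 2 * d
            new.extend([p1, p2, p3, b])
        pts = np.array(new)
    return LandmarkCurve("koch", pts)
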