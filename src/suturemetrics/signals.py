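"""Conversion of an open curve into a 1D signed-deviation signal.

The fractal-dimension and spectral estimators operate on a one-dimensional
profile rather than on raw 2D coordinates.  The profile used here is the
signed perpendicular distance of each semi-landmark from the endpoint chord,
indexed by semi-landmark order (uniform arc-length stations), *not* by
x-projection.  Indexing by station keeps looping sutures — whose deviation
is multi-valued in x — well defined: every station contributes exactly one
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DegenerateChordError", "DeviationSignal", "chord_frame", "deviation_signal"]


class DegenerateChordError(ValueError):
    """Curve endpoints coincide; no chord frame exists."""


@dataclass(frozen=True)
class DeviationSignal:
    """Signed perpendicular offsets of a curve from its endpoint chord.

    ``values[i]`` is the offset at station ``i`` (stations are uniform in
    arc length along the resampled curve); ``values[0] == values[-1] == 0``
    by construction.  ``chord_length`` is the endpoint separation in the
    same (post-Procrustes) units.
    """

    values: np.ndarray
    chord_length: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("signal must be a 1D array with >= 2 stations")
        if not self.chord_length > 0:
            raise DegenerateChordError("chord_length must be positive")
        object.__setattr__(self, "values", values)

    @property
    def n_stations(self) -> int:
        return self.values.size

    @property
    def stations(self) -> np.ndarray:
        return np.arange(self.values.size)


def chord_frame(coords: np.ndarray) -> np.ndarray:
    """Rigidly transform a curve so its first endpoint sits at the origin and
    its last endpoint on the positive x-axis.

    A pure rotation+translation: all pairwise distances are preserved.

    Raises
    ------
    DegenerateChordError
        If the endpoints coincide.
    """
    coords = np.asarray(coords, dtype=float)
    chord = coords[-1] - coords[0]
    length = np.linalg.norm(chord)
    if length == 0.0:
        raise DegenerateChordError("curve endpoints coincide")
    u = chord / length  # unit chord direction
    rot = np.array([[u[0], -u[1]], [u[1], u[0]]])  # maps u -> e_x via R^T
    return (coords - coords[0]) @ rot


def deviation_signal(coords: np.ndarray) -> DeviationSignal:
    """Signed perpendicular deviation of each semi-landmark from the chord.

    The curve should already be resampled to uniform arc-length stations.
    The values are the y-coordinates in the chord frame; endpoints are zero
    exactly.  Invariant to rotation and translation of the input.
    """
    framed = chord_frame(coords)
    values = framed[:, 1].copy()
    values[0] = 0.0
    values[-1] = 0.0  # endpoints lie on the chord by construction
    return DeviationSignal(values=values, chord_length=float(framed[-1, 0]))
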