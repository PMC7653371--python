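"""Generalized Procrustes analysis (GPA) for semi-landmark configurations.

Superimposition removes the non-shape components of landmark data:
translation (centroid to origin), size (centroid size scaled to 1) and
orientation (least-squares rotation to an evolving consensus).  Only proper
rotations are fitted — reflections are deliberately *not* removed, so mirror
-image sutures ('n' vs 'u' forms) remain distinct shapes, which is what lets
a downstream shape PCA separate them.

No semi-landmark sliding is performed; curves are aligned as fixed point
configurations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateShapeError",
    "ProcrustesSet",
    "centroid_size",
    "center_and_scale",
    "optimal_rotation",
    "gpa",
]


class DegenerateShapeError(ValueError):
    """All landmarks coincide; the shape has no size."""


@dataclass
class ProcrustesSet:
    """Result of a GPA run.

    Attributes
    ----------
    shapes
        ``(n_shapes, n_points, 2)`` aligned configurations, each centered at
        the origin with centroid size 1.
    mean_shape
        Consensus configuration, unit centroid size.
    iterations
        Number of consensus updates performed.
    residual
        Root-mean-square change of the consensus at the last iteration.
    converged
        False if ``max_iter`` was reached before ``residual < tol``.
    """

    shapes: np.ndarray
    mean_shape: np.ndarray
    iterations: int
    residual: float
    converged: bool


def centroid_size(shape: np.ndarray) -> float:
    """Root of the summed squared distances of landmarks to their centroid."""
    shape = np.asarray(shape, dtype=float)
    centered = shape - shape.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def center_and_scale(shape: np.ndarray) -> np.ndarray:
    """Translate the centroid to the origin and scale to unit centroid size.

    Raises
    ------
    DegenerateShapeError
        If all points are identical (centroid size 0).
    """
    shape = np.asarray(shape, dtype=float)
    centered = shape - shape.mean(axis=0)
    size = np.sqrt((centered**2).sum())
    if size == 0.0:
        raise DegenerateShapeError("all landmarks coincide")
    return centered / size

def optimal_rotation(shape: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotate ``shape`` to minimize the sum of squared distances to
    ``reference`` over *proper* rotations (det = +1; no reflection).

    Both configurations must be centered and have equal point counts.
    """
    shape = np.asarray(shape, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if shape.shape != reference.shape:
        raise ValueError(
            f"point count mismatch: {shape.shape} vs {reference.shape}"
        )
    # 2D Kabsch restricted to SO(2): the optimal angle has a closed form
    h = shape.T @ reference
    num = h[0, 1] - h[1, 0]
    den = h[0, 0] + h[1, 1]
    theta = np.arctan2(num, den)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, s], [-s, c]])
    return shape @ rot


def gpa(shapes, tol: float = 1e-8, max_iter: int = 100) -> ProcrustesSet:
    """Generalized Procrustes analysis of two or more configurations.

    Each shape is centered and scaled to unit centroid size, then iteratively
    rotated to the consensus (the normalized mean shape) until the consensus
    stops moving (RMS change < ``tol``) or ``max_iter`` is reached.  The
    total Procrustes sum of squares is non-increasing across iterations.

    Non-convergence is reported through ``converged=False`` on the result,
    not an exception.
    """
    arr = np.asarray([np.asarray(s, dtype=float) for s in shapes])
    if arr.ndim != 3 or arr.shape[0] < 2 or arr.shape[2] != 2:
        raise ValueError("gpa needs >= 2 shapes of identical (n_points, 2)")
    aligned = np.stack([center_and_scale(s) for s in arr])

    consensus = center_and_scale(aligned[0])
    iterations = 0
    residual = np.inf
    converged = False
    for iterations in range(1, max_iter + 1):
        aligned = np.stack([optimal_rotation(s, consensus) for s in aligned])
        new_consensus = center_and_scale(aligned.mean(axis=0))
        new_consensus = optimal_rotation(new_consensus, consensus)
        residual = float(
            np.sqrt(((new_consensus - consensus) ** 2).mean())
        )
        consensus = new_consensus
        if residual < tol:
            converged = True
            break
    # final orientation pass against the settled consensus
    aligned = np.stack([optimal_rotation(s, consensus) for s in aligned])
    return ProcrustesSet(
        shapes=aligned,
        mean_shape=consensus,
        iterations=iterations,
        residual=residual,
        converged=converged,
    )
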