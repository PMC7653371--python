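"""Reading, writing and resampling of 2D suture semi-landmark data.

A suture outline is an *open* polyline: an ordered sequence of (x, y)
semi-landmarks whose first and last points are the suture endpoints.  Two
on-disk dialects are supported:

* **TPS** — classic landmark records (``LM=``, point lines, ``ID=``).
* **CSV** — long format with columns ``specimen_id, point_index, x, y``.

Curves are typically digitized at an arbitrary density and then resampled to
a fixed number of equidistant semi-landmarks (500 by default throughout the
package) before any downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkCurve",
    "SutureIOError",
    "ParseError",
    "ValidationError",
    "DegenerateCurveError",
    "read_landmarks",
    "write_landmarks_csv",
    "resample_equidistant",
    "write_scores",
    "read_scores",
]


class SutureIOError(Exception):
    """Base class for landmark I/O failures."""


class ParseError(SutureIOError):
    """A record in a landmark file could not be parsed."""


class ValidationError(SutureIOError):
    """Parsed data violate a structural invariant (point counts, ids...)."""


class DegenerateCurveError(ValueError):
    """A curve has zero path length or coincident endpoints where a chord
    is required."""


@dataclass(frozen=True)
class LandmarkCurve:
    """Ordered 2D semi-landmarks for one open suture outline.

    Parameters
    ----------
    specimen_id
        Text label identifying the specimen/suture.
    coords
        ``(n_points, 2)`` float array; point order encodes the suture path
        and is never re-sorted.
    """

    specimen_id: str
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValidationError(
                f"{self.specimen_id}: coords must be (n, 2), got {coords.shape}"
            )
        if coords.shape[0] < 2:
            raise ValidationError(
                f"{self.specimen_id}: a curve needs at least 2 points, "
                f"got {coords.shape[0]}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValidationError(f"{self.specimen_id}: non-finite coordinates")
        object.__setattr__(self, "coords", coords)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def path_length(self) -> float:
        """Total polyline length (sum of consecutive segment lengths)."""
        return float(np.linalg.norm(np.diff(self.coords, axis=0), axis=1).sum())

    @property
    def chord_length(self) -> float:
        """Euclidean distance between the two suture endpoints."""
        return float(np.linalg.norm(self.coords[-1] - self.coords[0]))

    def with_coords(self, coords: np.ndarray) -> "LandmarkCurve":
        return LandmarkCurve(self.specimen_id, np.asarray(coords, dtype=float))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _read_tps(path: Path) -> list[LandmarkCurve]:
    curves: list[LandmarkCurve] = []
    n_expected: int | None = None
    points: list[tuple[float, float]] = []
    specimen_id: str | None = None
    record_start = 0

    def flush(lineno: int) -> None:
        nonlocal n_expected, points, specimen_id
        if n_expected is None:
            return
        if len(points) != n_expected:
            raise ParseError(
                f"{path}: record starting at line {record_start} declares "
                f"LM={n_expected} but has {len(points)} points"
            )
        sid = specimen_id if specimen_id is not None else f"record_{len(curves)}"
        try:
            curves.append(LandmarkCurve(sid, np.array(points)))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
        n_expected, points, specimen_id = None, [], None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush(lineno)
                record_start = lineno
                try:
                    n_expected = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad LM= line {line!r}") from exc
            elif upper.startswith("ID="):
                specimen_id = line.split("=", 1)[1].strip()
            elif "=" in line and not line[0].isdigit() and line[0] not in "+-.":
                continue  # IMAGE=, SCALE=, ... metadata we do not use
            else:
                if n_expected is None:
                    raise ParseError(f"{path}:{lineno}: point line outside a record")
                parts = line.split()
                if len(parts) != 2:
                    raise ParseError(f"{path}:{lineno}: expected 'x y', got {line!r}")
                try:
                    points.append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad coordinate {line!r}") from exc
    flush(-1)
    return curves


def _read_csv(path: Path) -> list[LandmarkCurve]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - reraise with file context
        raise ParseError(f"{path}: {exc}") from exc
    required = {"specimen_id", "point_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df[["x", "y"]].isna().any().any():
        bad = int(df.index[df[["x", "y"]].isna().any(axis=1)][0]) + 2
        raise ParseError(f"{path}: non-numeric/missing coordinate near line {bad}")
    curves = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("point_index")
        curves.append(LandmarkCurve(str(sid), grp[["x", "y"]].to_numpy(float)))
    return curves


def read_landmarks(path: str | Path, dialect: str = "csv") -> list[LandmarkCurve]:
    """Read semi-landmark curves from ``path``.

    Parameters
    ----------
    path
        Landmark file.
    dialect
        ``"tps"`` or ``"csv"``.

    Returns
    -------
    list of LandmarkCurve
        Curves in file order, point order preserved.

    Raises
    ------
    ParseError
        Malformed record (message names the line/record).
    ValidationError
        Fewer than 2 points in a record, or duplicate specimen ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tps":
        curves = _read_tps(path)
    elif dialect == "csv":
        curves = _read_csv(path)
    else:
        raise ValueError(f"unsupported dialect {dialect!r} (use 'tps' or 'csv')")
    seen: set[str] = set()
    for c in curves:
        if c.specimen_id in seen:
            raise ValidationError(f"{path}: duplicate specimen_id {c.specimen_id!r}")
        seen.add(c.specimen_id)
    return curves


def write_landmarks_csv(curves: Iterable[LandmarkCurve], path: str | Path) -> None:
    """Write curves in the package's CSV dialect (specimen_id, point_index, x, y)."""
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "specimen_id": c.specimen_id,
                    "point_index": np.arange(c.n_points),
                    "x": c.coords[:, 0],
                    "y": c.coords[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _points_at_arclength(coords: np.ndarray, cum: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Evaluate the polyline at arc-length positions ``s`` (piecewise linear)."""
    x = np.interp(s, cum, coords[:, 0])
    y = np.interp(s, cum, coords[:, 1])
    return np.column_stack([x, y])


def resample_equidistant(curve: LandmarkCurve, n: int) -> LandmarkCurve:
    """Resample a curve to exactly ``n`` semi-landmarks with equal consecutive
    spacing.

    Points stay on the input polyline (linear interpolation along arc
    length; no smoothing).  Spacing is made *equidistant in the Euclidean
    sense*: a fixed-point iteration reparameterizes the stations until all
    consecutive inter-point (chord) distances agree to ~1e-12 relative
    tolerance, so the returned polyline has uniform segment lengths.  First
    and last points equal the input endpoints exactly.

    Raises
    ------
    DegenerateCurveError
        If the total path length is zero.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    coords = curve.coords
    seg_len = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    total = float(seg_len.sum())
    if total == 0.0:
        raise DegenerateCurveError(f"{curve.specimen_id}: zero total path length")
    # drop zero-length segments (repeated digitized points)
    keep = np.concatenate([[True], seg_len > 0])
    coords = coords[keep]
    seg_len = seg_len[seg_len > 0]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    s = np.linspace(0.0, total, n)  # initial guess: equal arc length
    best_pts, best_spread = None, np.inf
    for _ in range(100):
        pts = _points_at_arclength(coords, cum, s)
        chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        mean = chords.mean()
        spread = (chords.max() - chords.min()) / mean if mean > 0 else 0.0
        if spread < best_spread:
            best_pts, best_spread = pts, spread
        if spread < 1e-13:
            break
        # remap stations so cumulative chord length becomes uniform
        c_cum = np.concatenate([[0.0], np.cumsum(chords)])
        s = np.interp(np.linspace(0.0, c_cum[-1], n), c_cum, s)
    pts = best_pts
    pts[0], pts[-1] = curve.coords[0], curve.coords[-1]
    return curve.with_coords(pts)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-specimen score table to CSV at full double precision.

    The table must be indexed by ``specimen_id`` or carry it as a column.
    Round-trips through :func:`read_scores` to < 1e-12.
    """
    if len(table) == 0:
        raise ValidationError("refusing to write an empty score table")
    df = table.copy()
    if df.index.name == "specimen_id":
        df = df.reset_index()
    if "specimen_id" not in df.columns:
        raise ValidationError("score table lacks a specimen_id column/index")
    df.to_csv(path, index=False, float_format="%.17g")


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a score table written by :func:`write_scores` (specimen_id index)."""
    df = pd.read_csv(path, float_precision="round_trip")
    return df.set_index("specimen_id")
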