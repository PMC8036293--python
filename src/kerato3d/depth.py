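"""Corneal depth from the lateral view.

The lateral corneal contour is reduced to three landmarks:

* ``p1`` — the apex, the contour point of maximal rightward protrusion
  (lateral views are canonicalized cornea-right);
* ``p2``/``p3`` — the upper and lower endpoints of the limbus chord, i.e.
  where the corneal arc meets the (vertical) chord, separated by roughly two
  iris radii (the iris radius comes from the frontal-view circle);
* ``C`` — the chord midpoint.

The corneal depth ``d`` is the leg of the right triangle with hypotenuse
``p1-p2`` and base ``C-p2``:  ``d = sqrt(|p1-p2|^2 - |p2-C|^2)``.  Whenever
``p1`` projects inside the chord segment this equals the perpendicular
distance from the apex to the chord line, which is the geometric oracle used
in tests.

Contour extraction: the silhouette is thresholded at the Otsu level and the
boundary is traced at subpixel resolution with marching squares
(``skimage.measure.find_contours``); the *rightmost profile* — the largest
boundary column crossing each image row — is the corneal contour function
used for landmarks and, later, for slope measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import find_contours

from .errors import DegenerateChordError, GeometryError, SegmentationError
from .io import Image2D, as_gray
from .iris import IrisCircle

__all__ = ["DepthLandmarks", "compute_depth", "find_depth_landmarks",
           "rightmost_profile"]

Point = tuple[float, float]


@dataclass
class DepthLandmarks:
    """Apex ``p1``, chord endpoints ``p2``/``p3``, chord midpoint ``C`` and
    corneal depth ``d`` (pixels).  All points are (row, col)."""

    p1: Point
    p2: Point
    p3: Point
    C: Point
    d: float

    def __post_init__(self) -> None:
        mid = ((self.p2[0] + self.p3[0]) / 2.0, (self.p2[1] + self.p3[1]) / 2.0)
        if not np.allclose(self.C, mid):
            raise GeometryError("C must be the midpoint of p2 and p3")
        if self.d < 0:
            raise GeometryError("depth must be non-negative")


def compute_depth(p1: Point, p2: Point, p3: Point) -> tuple[Point, float]:
    """Chord midpoint and corneal depth via the Pythagorean construction.

    The right triangle has hypotenuse ``p1 - p2`` and base equal to the
    projection of ``p1 - p2`` onto the chord direction, so

    ``d^2 = |p1 - p2|^2 - ((p1 - p2) . u)^2``,  ``u = (p3 - p2)/|p3 - p2|``.

    For an apex over the chord midpoint the base equals ``|p2 - C|`` and this
    reduces to the symmetric form; in general it equals the perpendicular
    distance from ``p1`` to the chord line, which is the oracle the tests
    compare against.  Raises :class:`DegenerateChordError` when ``p2 == p3``.
    """
    a1, a2, a3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    if np.allclose(a2, a3):
        raise DegenerateChordError("p2 and p3 coincide")
    c = (a2 + a3) / 2.0
    u = (a3 - a2) / np.linalg.norm(a3 - a2)
    hyp2 = float(np.sum((a1 - a2) ** 2))
    base2 = float(np.dot(a1 - a2, u) ** 2)
    rad = hyp2 - base2  # non-negative by Cauchy-Schwarz
    d = float(np.sqrt(max(rad, 0.0)))
    return (float(c[0]), float(c[1])), d


def rightmost_profile(
    lateral: Image2D | np.ndarray, rows: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Subpixel rightmost-boundary column for each image row.

    Thresholds at the Otsu level, traces boundaries with marching squares and
    takes, per row, the largest column where any boundary polyline crosses
    that row.  Returns ``(rows, cols)`` restricted to rows the boundary
    actually crosses.
    """
    gray = as_gray(lateral)
    span = float(gray.max() - gray.min())
    if span <= 0:
        raise SegmentationError("blank image: no contour")
    level = float(threshold_otsu(gray))
    contours = find_contours(gray, level=level)
    if not contours:
        raise SegmentationError("no contour found at the Otsu level")
    if rows is None:
        rows = np.arange(gray.shape[0], dtype=float)
    best = np.full(rows.shape, -np.inf)
    for contour in contours:
        r, c = contour[:, 0], contour[:, 1]
        for k in range(len(r) - 1):
            r0, r1 = r[k], r[k + 1]
            lo, hi = (r0, r1) if r0 <= r1 else (r1, r0)
            if hi == lo:
                hit = (rows == lo)
                if hit.any():
                    best[hit] = np.maximum(best[hit], max(c[k], c[k + 1]))
                continue
            inside = (rows >= lo) & (rows <= hi)
            if inside.any():
                t = (rows[inside] - r0) / (r1 - r0)
                cols = c[k] + t * (c[k + 1] - c[k])
                best[inside] = np.maximum(best[inside], cols)
    crossed = np.isfinite(best)
    if not crossed.any():
        raise SegmentationError("contour does not cross any image row")
    return rows[crossed], best[crossed]


def find_depth_landmarks(
    lateral: Image2D | np.ndarray, iris: IrisCircle
) -> DepthLandmarks:
    """Locate apex and chord endpoints on the lateral silhouette.

    ``p1`` is the profile maximum (rightmost contour point); ``p2``/``p3``
    are the profile points one iris radius above/below the apex row, where
    the corneal arc meets the limbus chord.
    """
    rows, cols = rightmost_profile(lateral)
    # apex = middle of the maximal plateau, so a flat (zero-depth) profile
    # yields its central row rather than an arbitrary endpoint
    plateau = np.nonzero(cols >= cols.max() - 1e-6)[0]
    i_apex = int(plateau[len(plateau) // 2])
    apex_row, apex_col = float(rows[i_apex]), float(cols[i_apex])
    R = float(iris.r)
    for target in (apex_row - R, apex_row + R):
        if target < rows.min() - 0.5 or target > rows.max() + 0.5:
            raise SegmentationError("limbus chord extends beyond the traced contour")
    col_at = lambda row: float(np.interp(row, rows, cols))
    p2: Point = (apex_row - R, col_at(apex_row - R))
    p3: Point = (apex_row + R, col_at(apex_row + R))
    p1: Point = (apex_row, apex_col)
    C, d = compute_depth(p1, p2, p3)
    return DepthLandmarks(p1=p1, p2=p2, p3=p3, C=C, d=d)
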