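"""Iris detection by circular Hough transform.

A circle with center ``(m, n)`` and radius ``r`` satisfies
``(x - m)^2 + (y - n)^2 = r^2`` and is traced by ``x = m + r cos(a)``,
``y = n + r sin(a)``.  The detector votes over the 3D parameter grid
``(m, n, r)`` at 1 px resolution and returns the arg-max.

Vote definition (shared by the detector and the brute-force reference): an
edge pixel at ``(row, col)`` votes for ``(m, n, r)`` iff
``round(hypot(col - m, row - n)) == r``.  Votes are normalized by the number
of lattice cells in the radius-``r`` ring, so the score is the supported
fraction of the circle, in [0, 1].

Coordinate convention: images are 0-based ``(row, col)``; ``m`` is the center
*column* (x) and ``n`` the center *row* (y), preserving the usual x/y reading
of the circle equation.

The fast path computes the accumulator per radius as a convolution of the
binary edge map with the ring's indicator kernel;
:func:`bruteforce_accumulator` recomputes the identical counts by direct
enumeration over the parameter grid and is used as an independent oracle in
tests and in the acceptance experiments.

Tie-break: among equal normalized scores the smallest radius wins, then the
lexicographically smallest ``(n, m)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve
from skimage.feature import canny

from .errors import GeometryError, NoCircleFound
from .io import Image2D, as_gray

__all__ = [
    "IrisCircle",
    "detect_iris",
    "iris_landmarks",
    "edge_map",
    "bruteforce_accumulator",
]


@dataclass(frozen=True)
class IrisCircle:
    """Detected iris circle: center column ``m``, center row ``n``, radius
    ``r`` (pixels), and the normalized accumulator score ``votes``."""

    m: int
    n: int
    r: int
    votes: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise GeometryError("iris radius must be positive")
        if not 0.0 <= self.votes <= 1.0:
            raise GeometryError("votes must be normalized to [0, 1]")


def edge_map(image: Image2D | np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Binary edge map: Gaussian-gradient magnitude with non-maximum
    suppression and hysteresis (Canny)."""
    gray = as_gray(image)
    span = float(gray.max() - gray.min())
    if span <= 0:
        return np.zeros(gray.shape, dtype=bool)
    norm = (gray - gray.min()) / span
    return canny(norm, sigma=sigma)


@lru_cache(maxsize=128)
def _ring_offsets(r: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Lattice offsets (drow, dcol) with round(hypot) == r, and their count."""
    d = np.arange(-r - 1, r + 2)
    dr, dc = np.meshgrid(d, d, indexing="ij")
    mask = np.rint(np.hypot(dr, dc)).astype(int) == r
    return dr[mask], dc[mask], int(mask.sum())


def _ring_kernel(r: int) -> np.ndarray:
    dr, dc, _ = _ring_offsets(r)
    size = 2 * (r + 1) + 1
    k = np.zeros((size, size), dtype=np.float32)
    k[dr + r + 1, dc + r + 1] = 1.0
    return k


def _center_validity(shape: tuple[int, int], r: int) -> np.ndarray:
    """Centers for which the radius-r circle lies fully inside the image."""
    rows, cols = shape
    ok = np.zeros(shape, dtype=bool)
    if rows > 2 * r and cols > 2 * r:
        ok[r : rows - r, r : cols - r] = True
    return ok


def detect_iris(
    image: Image2D | np.ndarray,
    radius_range: tuple[int, int],
    edge_sigma: float = 2.0,
    min_support: float = 0.25,
) -> IrisCircle:
    """Detect the strongest circle in the frontal image.

    Parameters
    ----------
    radius_range : (r_min, r_max), inclusive, pixels.
    min_support : minimum normalized vote fraction; below it
        :class:`NoCircleFound` is raised.
    """
    gray = as_gray(image)
    r_min, r_max = int(radius_range[0]), int(radius_range[1])
    if r_min < 3:
        raise GeometryError("r_min must be >= 3")
    if r_max >= min(gray.shape) / 2:
        raise GeometryError("r_max must be < min(image dims) / 2")
    if r_min > r_max:
        raise GeometryError("empty radius range")
    edges = edge_map(gray, sigma=edge_sigma)
    if not edges.any():
        raise NoCircleFound("no edges in image")

    e = edges.astype(np.float32)
    best: tuple[int, int, int, int, int] | None = None  # (count, ring, n, m, r)
    for r in range(r_min, r_max + 1):  # ascending r implements the radius tie-break
        acc = fftconvolve(e, _ring_kernel(r), mode="same")
        counts = np.rint(acc).astype(np.int64)  # exact integer vote counts
        counts[~_center_validity(gray.shape, r)] = -1
        idx = int(np.argmax(counts))  # row-major => lexicographic (n, m) tie-break
        n, m = np.unravel_index(idx, counts.shape)
        count = int(counts[n, m])
        if count < 0:
            continue
        ring = _ring_offsets(r)[2]
        # compare count/ring fractions exactly via cross-multiplication
        if best is None or count * best[1] > best[0] * ring:
            best = (count, ring, int(n), int(m), r)
    if best is None:
        raise NoCircleFound("no center admits a fully-inside circle")
    count, ring, n, m, r = best
    votes = count / ring
    if votes < min_support:
        raise NoCircleFound(
            f"best circle supported by only {votes:.2f} of its circumference"
        )
    return IrisCircle(m=m, n=n, r=r, votes=votes)


def bruteforce_accumulator(
    edges: np.ndarray, radius_range: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Reference accumulator by direct enumeration (oracle; O(centers * edges)).

    For every candidate center the rounded distance to each edge pixel is
    histogrammed over radii.  Returns ``(counts, valid)`` with shape
    ``(n_radii, rows, cols)``; invalid (not fully inside) entries are -1 in
    ``counts``.
    """
    r_min, r_max = int(radius_range[0]), int(radius_range[1])
    rows, cols = edges.shape
    er, ec = np.nonzero(edges)
    n_r = r_max - r_min + 1
    counts = np.zeros((n_r, rows, cols), dtype=np.int64)
    for n in range(rows):
        d_row2 = (er - n) ** 2
        for m in range(cols):
            dist = np.rint(np.sqrt(d_row2 + (ec - m) ** 2)).astype(int)
            in_range = (dist >= r_min) & (dist <= r_max)
            if in_range.any():
                counts[:, n, m] = np.bincount(
                    dist[in_range] - r_min, minlength=n_r
                )
    valid = np.stack(
        [_center_validity(edges.shape, r) for r in range(r_min, r_max + 1)]
    )
    counts[~valid] = -1
    return counts, valid


def bruteforce_argmax(
    edges: np.ndarray, radius_range: tuple[int, int]
) -> IrisCircle:
    """Arg-max of the brute-force accumulator with the detector's tie-breaks."""
    r_min, _ = radius_range
    counts, _ = bruteforce_accumulator(edges, radius_range)
    best = None
    for ri in range(counts.shape[0]):
        r = r_min + ri
        ring = _ring_offsets(r)[2]
        idx = int(np.argmax(counts[ri]))
        n, m = np.unravel_index(idx, counts[ri].shape)
        count = int(counts[ri, n, m])
        if count < 0:
            continue
        if best is None or count * best[1] > best[0] * ring:
            best = (count, ring, int(n), int(m), r)
    if best is None:
        raise NoCircleFound("no valid candidate")
    count, ring, n, m, r = best
    return IrisCircle(m=m, n=n, r=r, votes=count / ring)


def iris_landmarks(
    circle: IrisCircle,
) -> tuple[tuple[float, float], float, tuple[tuple[float, float], tuple[float, float]]]:
    """Center, radius, and the top/bottom limbus points on the circumference.

    The limbus points are the circle evaluated at a = -90 and +90 degrees
    (``x = m + r cos a``, ``y = n + r sin a``), i.e. the topmost and
    bottommost circumference points.  Returned in (row, col) coordinates.
    """
    center = (float(circle.n), float(circle.m))
    top = (float(circle.n - circle.r), float(circle.m))
    bottom = (float(circle.n + circle.r), float(circle.m))
    return center, float(circle.r), (top, bottom)
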