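"""Fusion of orthogonal frontal/lateral views into 3D corneal points.

Coordinate model
----------------
The global 3D frame is anchored to the **frontal** image: global ``x`` is the
frontal column, global ``y`` the frontal row (shared vertical axis of both
views), and global ``z`` the depth axis, which only the **lateral** view
observes (its column measures protrusion).  The two image planes are
orthogonal; a single homogeneous translation ``T = (tx, ty, tz)`` places the
lateral plane in the global frame:

* a frontal point ``(x1, y1)`` lifts to ``(x1, y1, 0)``;
* a lateral point ``(x2, y2)`` lifts to ``(tx, y2 + ty, x2 + tz)``.

``tx`` is the global x of the (sagittal) lateral plane, ``ty`` the vertical
offset aligning lateral rows with frontal rows, ``tz`` the depth origin
(pipeline convention: the limbus chord plane maps to ``z = 0``).

:func:`estimate_transform` minimizes the summed squared 3D distance between
the frontal-lifted and lateral-lifted versions of each correspondence; for a
pure translation the minimizer is the component-wise mean of the residuals,
so perfectly consistent correspondences are recovered exactly, with zero
residual, from a single pair.

Fused points take ``x``/``y`` from the frontal view and ``z`` from the
lateral view: ``(x3, y3, z3) = (x1, y1, x2 + tz)`` (for consistent inputs
``y2 + ty == y1``; otherwise the two estimates of the shared coordinate are
averaged).  Given ``T`` the mapping is invertible per point, and the
round-trip projection error is zero for consistent inputs.

:func:`ssd_match` scores a constructed volume against a stored reference by
the sum of squared intensity differences
``E = sum (I_construct - I_stored)^2``; picking the reference with minimal
``E`` implements volume matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.ndimage import gaussian_filter, zoom

from .errors import DegenerateSurfaceError, InsufficientMatchesError
from .io import Volume3D

__all__ = [
    "OrthoTransform",
    "FusedPoint",
    "estimate_transform",
    "fuse_points",
    "project_back",
    "rasterize_volume",
    "ssd_match",
    "rotate_volume",
]


@dataclass(frozen=True)
class OrthoTransform:
    """Translation placing the lateral image frame in the global frame."""

    tx: float
    ty: float
    tz: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.tx, self.ty, self.tz])):
            raise ValueError("transform offsets must be finite")

    def as_matrix(self) -> np.ndarray:
        """4x4 homogeneous translation matrix."""
        m = np.eye(4)
        m[:3, 3] = (self.tx, self.ty, self.tz)
        return m


@dataclass(frozen=True)
class FusedPoint:
    """A 3D point with its source 2D observations."""

    x3: float
    y3: float
    z3: float
    source_frontal: tuple[float, float]  # (x1, y1)
    source_lateral: tuple[float, float]  # (x2, y2)

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x3, self.y3, self.z3)


def _lift(frontal_pts: np.ndarray, lateral_pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(frontal_pts, dtype=float).reshape(-1, 2)
    l = np.asarray(lateral_pts, dtype=float).reshape(-1, 2)
    if f.shape != l.shape:
        raise ValueError("frontal and lateral point lists differ in length")
    f3 = np.column_stack([f[:, 0], f[:, 1], np.zeros(len(f))])
    l3 = np.column_stack([np.zeros(len(l)), l[:, 1], l[:, 0]])
    return f3, l3


def estimate_transform(
    frontal_pts: np.ndarray, lateral_pts: np.ndarray, matches=None
) -> OrthoTransform:
    """Least-squares translation between lifted correspondences.

    Points are ``(x, y)`` image coordinates (column, row).  When ``matches``
    (a :class:`~kerato3d.features.MatchSet`) is given, ``frontal_pts`` and
    ``lateral_pts`` are indexed by its pairs; otherwise they are taken as
    already corresponding row-for-row.

    Closed form: ``T = mean(lift_frontal - lift_lateral)`` component-wise.
    """
    f = np.asarray(frontal_pts, dtype=float).reshape(-1, 2)
    l = np.asarray(lateral_pts, dtype=float).reshape(-1, 2)
    if matches is not None:
        if len(matches.pairs) == 0:
            raise InsufficientMatchesError("no correspondences to estimate from")
        ia = [p[0] for p in matches.pairs]
        ib = [p[1] for p in matches.pairs]
        f, l = f[ia], l[ib]
    if len(f) == 0:
        raise InsufficientMatchesError("no correspondences to estimate from")
    f3, l3 = _lift(f, l)
    t = (f3 - l3).mean(axis=0)
    return OrthoTransform(tx=float(t[0]), ty=float(t[1]), tz=float(t[2]))


def transform_residual(
    t: OrthoTransform, frontal_pts: np.ndarray, lateral_pts: np.ndarray
) -> float:
    """Root-mean-square 3D distance between lifted correspondences under t."""
    f3, l3 = _lift(np.asarray(frontal_pts), np.asarray(lateral_pts))
    diff = f3 - (l3 + np.array([t.tx, t.ty, t.tz]))
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def fuse_points(
    frontal_pts: np.ndarray, lateral_pts: np.ndarray, t: OrthoTransform
) -> list[FusedPoint]:
    """Map corresponding 2D observations to 3D points.

    ``x3 = x1``, ``z3 = x2 + tz``; the shared vertical coordinate is the
    average of the frontal row and the aligned lateral row (identical for
    consistent inputs).
    """
    f = np.asarray(frontal_pts, dtype=float).reshape(-1, 2)
    l = np.asarray(lateral_pts, dtype=float).reshape(-1, 2)
    if f.shape != l.shape:
        raise ValueError("frontal and lateral point lists differ in length")
    out = []
    for (x1, y1), (x2, y2) in zip(f, l):
        y3 = 0.5 * (y1 + (y2 + t.ty))
        out.append(
            FusedPoint(
                x3=float(x1),
                y3=float(y3),
                z3=float(x2 + t.tz),
                source_frontal=(float(x1), float(y1)),
                source_lateral=(float(x2), float(y2)),
            )
        )
    return out


def project_back(
    points: list[FusedPoint], t: OrthoTransform
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the fusion: recover the frontal and lateral 2D observations."""
    xyz = np.array([p.xyz for p in points], dtype=float).reshape(-1, 3)
    frontal = xyz[:, :2].copy()  # (x1, y1)
    lateral = np.column_stack([xyz[:, 2] - t.tz, xyz[:, 1] - t.ty])  # (x2, y2)
    return frontal, lateral


def rasterize_volume(
    points: list[FusedPoint],
    shape: tuple[int, int, int],
    smoothing_sigma: float = 1.0,
    shell_half_width: float = 1.5,
) -> Volume3D:
    """Rasterize fused surface points into a voxel volume.

    The points are treated as samples of a corneal elevation surface
    ``z(x, y)``; a thin-plate spline interpolates the surface over the
    (frontal) x-y grid spanned by the points, a shell of unit intensity is
    deposited around it, and a Gaussian filter of ``smoothing_sigma`` voxels
    is applied.  Deterministic.

    Raises :class:`DegenerateSurfaceError` when fewer than 4 points are given
    or all points are coplanar.
    """
    if len(points) < 4:
        raise DegenerateSurfaceError("need at least 4 points")
    xyz = np.array([p.xyz for p in points], dtype=float)
    centered = xyz - xyz.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise DegenerateSurfaceError("all points are coplanar")

    nx, ny, nz = shape
    # map the point cloud into the voxel grid with a small margin
    lo = xyz.min(axis=0)
    hi = xyz.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    margin = 0.05
    scale = np.array([nx, ny, nz]) * (1 - 2 * margin) / span
    s = float(scale.min())  # isotropic: preserve shape
    offset = lo - margin * np.array([nx, ny, nz]) / s
    g = (xyz - offset) * s  # grid coordinates

    interp = RBFInterpolator(g[:, :2], g[:, 2], kernel="thin_plate_spline")
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    flat = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    # only evaluate inside the x-y footprint of the points
    xy_lo, xy_hi = g[:, :2].min(axis=0), g[:, :2].max(axis=0)
    inside = np.all((flat >= xy_lo - 0.5) & (flat <= xy_hi + 0.5), axis=1)
    z_surf = np.full(nx * ny, np.nan)
    if inside.any():
        z_surf[inside] = interp(flat[inside])
    z_surf = z_surf.reshape(nx, ny)

    vox = np.zeros(shape, dtype=np.float32)
    zc = np.arange(nz, dtype=float)
    valid = np.isfinite(z_surf)
    dist = np.abs(zc[None, None, :] - np.where(valid, z_surf, -1e9)[..., None])
    vox[dist <= shell_half_width] = 1.0
    if smoothing_sigma > 0:
        vox = gaussian_filter(vox, sigma=smoothing_sigma)
    return Volume3D(vox, spacing=1.0 / s)


def points_to_frame(points: list[FusedPoint]):
    """Tidy table of fused points (x3, y3, z3 + source 2D observations),
    ready for ``DataFrame.to_csv``."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x3": [p.x3 for p in points],
            "y3": [p.y3 for p in points],
            "z3": [p.z3 for p in points],
            "src_frontal_x": [p.source_frontal[0] for p in points],
            "src_frontal_y": [p.source_frontal[1] for p in points],
            "src_lateral_x": [p.source_lateral[0] for p in points],
            "src_lateral_y": [p.source_lateral[1] for p in points],
        }
    )


def ssd_match(constructed: Volume3D, reference: Volume3D) -> float:
    """Sum of squared intensity differences between two volumes.

    The reference is resampled (trilinear) onto the constructed grid when the
    shapes differ.  Symmetric in its arguments for equal shapes, and zero for
    identical volumes.
    """
    a = constructed.voxels.astype(np.float64)
    b = reference.voxels.astype(np.float64)
    if a.shape != b.shape:
        factors = [sa / sb for sa, sb in zip(a.shape, b.shape)]
        b = zoom(b, factors, order=1)
        if b.shape != a.shape:  # zoom rounding left a 1-voxel mismatch
            b = b[tuple(slice(0, s) for s in a.shape)]
            pad = [(0, sa - sb) for sa, sb in zip(a.shape, b.shape)]
            b = np.pad(b, pad, mode="edge")
    return float(np.sum((a - b) ** 2))


def rotate_volume(volume: Volume3D, angle_deg: float, axes: tuple[int, int] = (0, 2)) -> Volume3D:
    """Rigidly rotate a volume in the plane of ``axes`` (utility; trilinear)."""
    from scipy.ndimage import rotate

    out = rotate(volume.voxels, angle_deg, axes=axes, reshape=False, order=1)
    return Volume3D(out.astype(np.float32), spacing=volume.spacing)
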