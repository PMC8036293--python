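"""Scale-invariant keypoints and cross-view descriptor matching.

Keypoints are local extrema of a difference-of-Gaussian pyramid, filtered by
contrast, each carrying a subpixel position, a scale, a dominant gradient
orientation and a 128-dimensional gradient-histogram descriptor (4x4 spatial
bins x 8 orientation bins, L2-normalized).  The detector/descriptor is the
standard scale-invariant feature transform, delegated to
``skimage.feature.SIFT``; this module fixes the parameterization, the
container types and the matching semantics.

Matching uses the nearest-neighbor *ratio test*: a keypoint in ``a`` is
paired with its closest descriptor in ``b`` only when that distance is
sufficiently smaller than the second-closest (``d1/d2 < ratio_threshold``,
canonical threshold 0.8).  Each source keypoint appears in at most one pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import circle_perimeter
from skimage.feature import SIFT

from .errors import ConfigurationError
from .io import Image2D, as_gray

__all__ = ["Keypoint", "MatchSet", "extract_keypoints", "match_keypoints",
           "dense_feature_overlay"]

#: Distance cap used when the candidate set has a single descriptor and the
#: ratio test is undefined.  Descriptors are unit-norm, so distances lie in
#: [0, 2]; 0.5 is a conservative "clearly similar" bound.
SINGLE_CANDIDATE_DISTANCE_CAP = 0.5


@dataclass(frozen=True)
class Keypoint:
    """One scale-space feature: subpixel (row, col), scale sigma, orientation
    in degrees [0, 360), unit-norm descriptor."""

    position: tuple[float, float]
    scale: float
    orientation: float
    descriptor: np.ndarray

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        norm = float(np.linalg.norm(self.descriptor))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError("descriptor must be L2-normalized")


@dataclass
class MatchSet:
    """Ratio-test matches: (index in a, index in b, distance, ratio)."""

    pairs: list[tuple[int, int, float, float]]
    ratio_threshold: float

    def __len__(self) -> int:
        return len(self.pairs)

    def positions(
        self, a: list[Keypoint], b: list[Keypoint]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Matched (row, col) coordinate arrays in each image."""
        if not self.pairs:
            return np.empty((0, 2)), np.empty((0, 2))
        pa = np.array([a[i].position for i, _, _, _ in self.pairs])
        pb = np.array([b[j].position for _, j, _, _ in self.pairs])
        return pa, pb


def extract_keypoints(
    image: Image2D | np.ndarray,
    n_octaves: int = 4,
    contrast_threshold: float = 0.013,
    n_scales: int = 3,
    sigma_min: float = 1.6,
) -> list[Keypoint]:
    """Detect scale-space keypoints with orientations and descriptors.

    Deterministic for a fixed input.  A featureless (flat) image yields an
    empty list.  ``contrast_threshold`` is the difference-of-Gaussian
    contrast cut: raising it never increases the keypoint count.
    """
    gray = as_gray(image)
    if min(gray.shape) < 64:
        raise ConfigurationError("image must be at least 64x64 for keypoints")
    # the pyramid needs min_dim / 2^(n_octaves-1) to stay meaningfully large
    if min(gray.shape) // 2 ** (n_octaves - 1) < 8:
        raise ConfigurationError("image too small for the requested octave count")
    span = float(gray.max() - gray.min())
    if span <= 0:
        return []
    norm = (gray - gray.min()) / span
    sift = SIFT(
        upsampling=1,
        n_octaves=n_octaves,
        n_scales=n_scales,
        sigma_min=sigma_min,
        c_dog=contrast_threshold,
    )
    try:
        sift.detect_and_extract(norm)
    except RuntimeError:  # skimage raises when nothing survives filtering
        return []
    kps: list[Keypoint] = []
    for pos, sigma, ori, desc in zip(
        sift.positions, sift.sigmas, sift.orientations, sift.descriptors
    ):
        d = desc.astype(np.float64)
        n = np.linalg.norm(d)
        if n == 0:
            continue
        deg = float(np.rad2deg(ori)) % 360.0
        kps.append(
            Keypoint(
                position=(float(pos[0]), float(pos[1])),
                scale=float(sigma),
                orientation=deg,
                descriptor=(d / n).astype(np.float32),
            )
        )
    return kps


def match_keypoints(
    a: list[Keypoint], b: list[Keypoint], ratio_threshold: float = 0.8
) -> MatchSet:
    """Nearest-neighbor ratio-test matching from ``a`` into ``b``.

    Empty inputs yield an empty MatchSet.  With a single candidate in ``b``
    the ratio is undefined and an absolute distance cap is used instead.
    """
    if ratio_threshold < 0:
        raise ValueError("ratio_threshold must be non-negative")
    if not a or not b:
        return MatchSet(pairs=[], ratio_threshold=ratio_threshold)
    da = np.stack([k.descriptor for k in a]).astype(np.float64)
    db = np.stack([k.descriptor for k in b]).astype(np.float64)
    if da.shape[1] != db.shape[1]:
        raise ValueError("descriptor lengths differ")
    pairs: list[tuple[int, int, float, float]] = []
    if len(b) == 1:
        if ratio_threshold > 0:
            dists = np.linalg.norm(da - db[0], axis=1)
            for i, dist in enumerate(dists):
                if dist < SINGLE_CANDIDATE_DISTANCE_CAP:
                    pairs.append((i, 0, float(dist), 0.0))
        return MatchSet(pairs=pairs, ratio_threshold=ratio_threshold)
    tree = cKDTree(db)
    dists, idx = tree.query(da, k=2)
    for i in range(len(a)):
        d1, d2 = float(dists[i, 0]), float(dists[i, 1])
        ratio = 0.0 if d1 == 0.0 else (np.inf if d2 == 0.0 else d1 / d2)
        if ratio < ratio_threshold:
            pairs.append((i, int(idx[i, 0]), d1, float(ratio)))
    return MatchSet(pairs=pairs, ratio_threshold=ratio_threshold)


def dense_feature_overlay(
    image: Image2D | np.ndarray, keypoints: list[Keypoint]
) -> Image2D:
    """Diagnostic copy of the image with a circle drawn at each keypoint,
    radius proportional to the keypoint scale.  Pixels outside the drawn
    circles are untouched."""
    gray = as_gray(image).copy()
    for kp in keypoints:
        r, c = int(round(kp.position[0])), int(round(kp.position[1]))
        radius = max(1, int(round(2.0 * kp.scale)))
        rr, cc = circle_perimeter(r, c, radius, shape=gray.shape)
        gray[rr, cc] = 0.0
    return Image2D(gray)
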