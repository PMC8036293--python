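"""Image and volume containers plus file I/O.

Conventions used across the package:

* 2D images are stored row-major with the origin at the top-left, 0-based
  ``(row, col)`` indices.  Intensities are ``float32`` on a nominal 0-255
  scale (8-bit images load without rescaling).
* 3D volumes are ``float32`` arrays indexed ``I[x, y, z]`` with isotropic
  voxel spacing; intensities live on a nominal 0-1 scale where *darker grey
  encodes higher corneal elevation*.
* Lateral views are canonicalized so the face is on the left and the cornea
  protrudes to the right.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "Image2D",
    "Volume3D",
    "as_gray",
    "load_image",
    "save_image",
    "load_volume",
    "save_volume",
    "canonicalize_lateral",
]


@dataclass
class Image2D:
    """A 2D eye image: ``pixels[row, col]`` (or ``[row, col, 3]`` for RGB)."""

    pixels: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("Image2D expects a 2D grid or a (row, col, 3) RGB grid")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError("RGB images must have exactly 3 channels")
        if min(self.pixels.shape[:2]) < 32:
            raise ValueError("images must be at least 32x32 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image intensities must be finite")

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else 3

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class Volume3D:
    """A 3D corneal volume: ``voxels[x, y, z]`` with isotropic spacing."""

    voxels: np.ndarray
    spacing: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError("Volume3D expects a 3D grid")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def as_gray(image: Image2D | np.ndarray) -> np.ndarray:
    """Return a single-channel float array; RGB is converted by luminance."""
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image, dtype=np.float32)
    if px.ndim == 3:
        # ITU-R 601 luma weights
        px = px @ np.array([0.299, 0.587, 0.114], dtype=px.dtype)
    return px.astype(np.float32)


def load_image(path: str | Path) -> Image2D:
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    return Image2D(arr.astype(np.float32))


def save_image(image: Image2D | np.ndarray, path: str | Path) -> None:
    """Write as 8-bit grayscale (or RGB) PNG/TIFF."""
    px = image.pixels if isinstance(image, Image2D) else np.asarray(image)
    out = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    iio.imwrite(path, out)


def load_volume(path: str | Path) -> Volume3D:
    img = nib.load(str(path))
    spacing = float(img.header.get_zooms()[0])
    return Volume3D(np.asanyarray(img.dataobj).astype(np.float32), spacing=spacing)


def save_volume(volume: Volume3D, path: str | Path) -> None:
    affine = np.diag([volume.spacing] * 3 + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), str(path))


def canonicalize_lateral(image: Image2D) -> Image2D:
    """Flip the lateral view horizontally if needed so the cornea points right.

    Heuristic: the (dark) head silhouette should occupy the left half.  If the
    column centroid of below-median intensity lies right of the image center,
    the view is mirrored.
    """
    gray = as_gray(image)
    fg = gray < np.median(gray)
    if not fg.any():
        return image
    cols = np.nonzero(fg)[1]
    if cols.mean() > gray.shape[1] / 2:
        px = image.pixels[:, ::-1].copy()
        return Image2D(px, pixel_size=image.pixel_size)
    return image
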