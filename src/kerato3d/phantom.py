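"""Synthetic eye phantoms with analytically known ground truth.

The rest of the pipeline (iris detection, depth triangle, 3D fusion,
curvature staging, CNN classification) is validated against parametric
phantoms rather than clinical photographs.  A phantom is defined by its
geometry, never by photorealism:

* **Frontal view** — a dark iris disc (with darker pupil) of known center and
  radius on a lighter sclera background.
* **Lateral view** — a profile silhouette whose corneal contour is either a
  *spherical cap* (normal cornea) or a pair of *straight conical flanks*
  (keratoconus).  Straight flanks make the maximum tangent slope of the
  contour exactly the requested steepness angle.
* **Volume** — the matching corneal elevation surface rasterized as a voxel
  shell, with darker grey encoding higher elevation.

Geometry of the lateral contour, with ``R`` the iris radius and ``s`` the
steepness angle (the greatest angle between the corneal surface tangent and
the limbus plane):

* spherical cap: circle radius ``Rc = R / sin(s)``, apex height
  ``h = R * tan(s/2)``; the maximum slope ``s`` occurs where the arc meets
  the limbus chord.
* cone: apex height ``h = R * tan(s)``; the flank slope is ``s`` everywhere.

All renders are deterministic given the spec's seed; ``noise_sigma == 0``
renders ignore the seed entirely.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, GeometryError
from .io import Image2D, Volume3D, save_image, save_volume

__all__ = [
    "STAGES",
    "DEFAULT_STAGE_RANGES",
    "EyePhantomSpec",
    "LateralTruth",
    "PhantomCase",
    "render_frontal",
    "render_lateral",
    "render_volume",
    "generate_cohort",
    "write_cohort",
    "stage_for_steepness",
]

#: Canonical class order used everywhere (reports, CNN one-hot encoding).
STAGES = ("normal", "mild", "moderate", "severe")

#: Default ground-truth steepness ranges per stage (degrees).  Keratoconic
#: ranges keep 1-2 degree guard bands around the 45/52 degree staging
#: boundaries so a phantom's label is never ambiguous.
DEFAULT_STAGE_RANGES: dict[str, tuple[float, float]] = {
    "normal": (30.0, 40.0),
    "mild": (41.0, 44.0),
    "moderate": (46.0, 51.0),
    "severe": (53.0, 65.0),
}

# Rendering intensities, 0-255 scale.
_SCLERA, _IRIS, _PUPIL = 200.0, 90.0, 40.0
_BODY, _BACKGROUND = 60.0, 220.0
_PUPIL_FRACTION = 0.45  # pupil radius as a fraction of the iris radius


def stage_for_steepness(steepness_deg: float, cone: bool) -> str:
    """Stage implied by a steepness angle under the 45/52 degree thresholds."""
    if not cone:
        return "normal"
    if steepness_deg < 45.0:
        return "mild"
    if steepness_deg <= 52.0:
        return "moderate"
    return "severe"


def _apex_height(iris_radius: float, steepness_deg: float, cone: bool) -> float:
    s = np.deg2rad(steepness_deg)
    return float(iris_radius * (np.tan(s) if cone else np.tan(s / 2.0)))


@dataclass
class EyePhantomSpec:
    """Parametric ground truth for one synthetic eye.

    ``cornea_apex_height`` is derived from ``steepness_angle_deg`` and
    ``iris_radius`` when left ``None``; an explicitly supplied value must be
    consistent with the shape model (1 px tolerance).
    """

    image_size: int = 256
    iris_center: tuple[float, float] = (128.0, 128.0)  # (row, col)
    iris_radius: float = 45.0
    steepness_angle_deg: float = 35.0
    stage_label: str = "normal"
    cornea_apex_height: float | None = None
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stage_label not in STAGES:
            raise ConfigurationError(f"unknown stage label {self.stage_label!r}")
        if self.iris_radius <= 0:
            raise GeometryError("iris_radius must be positive")
        if not 0.0 < self.steepness_angle_deg < 90.0:
            raise GeometryError("steepness_angle_deg must lie in (0, 90)")
        expected = _apex_height(self.iris_radius, self.steepness_angle_deg, self.is_cone)
        if self.cornea_apex_height is None:
            self.cornea_apex_height = expected
        elif abs(self.cornea_apex_height - expected) > 1.0:
            raise GeometryError(
                f"cornea_apex_height {self.cornea_apex_height:.2f} inconsistent with "
                f"steepness {self.steepness_angle_deg:.1f} deg (expected {expected:.2f})"
            )
        if self.cornea_apex_height < 0:
            raise GeometryError("cornea_apex_height must be non-negative")
        implied = stage_for_steepness(self.steepness_angle_deg, self.is_cone)
        if implied != self.stage_label:
            raise ConfigurationError(
                f"stage_label {self.stage_label!r} inconsistent with steepness "
                f"{self.steepness_angle_deg:.1f} deg (implies {implied!r})"
            )
        # normal corneas are spherical caps below the mild staging threshold
        if not self.is_cone and self.steepness_angle_deg >= 45.0:
            raise ConfigurationError(
                "normal phantoms must keep steepness below the 45 degree threshold"
            )

    @property
    def is_cone(self) -> bool:
        return self.stage_label != "normal"

    def lateral_profile(self, rows: np.ndarray, chord_col: float) -> np.ndarray:
        """Analytic rightmost-column profile of the lateral corneal contour.

        Returns, for each row, the column of the silhouette boundary: the
        chord column outside the limbus span, cap/cone contour inside.
        """
        rows = np.asarray(rows, dtype=float)
        u = rows - self.iris_center[0]
        R, h = self.iris_radius, float(self.cornea_apex_height)
        prof = np.full_like(u, chord_col)
        inside = np.abs(u) <= R
        if self.is_cone:
            prof[inside] = chord_col + h * (1.0 - np.abs(u[inside]) / R)
        else:
            Rc = (R * R + h * h) / (2.0 * h) if h > 0 else np.inf
            if np.isfinite(Rc):
                bulge = np.sqrt(np.maximum(Rc * Rc - u[inside] ** 2, 0.0)) - (Rc - h)
                prof[inside] = chord_col + np.maximum(bulge, 0.0)
        return prof

    @property
    def chord_col(self) -> float:
        """Column of the limbus chord in the lateral view."""
        return float(round(0.40 * self.image_size))


@dataclass
class LateralTruth:
    """Ground-truth landmarks of a rendered lateral view, (row, col) coords."""

    apex: tuple[float, float]
    p2: tuple[float, float]
    p3: tuple[float, float]
    chord_col: float
    apex_height: float


@dataclass
class PhantomCase:
    case_id: str
    spec: EyePhantomSpec
    frontal: Image2D
    lateral: Image2D
    lateral_truth: LateralTruth
    volume: Volume3D
    stage: str


def _check_frontal_geometry(spec: EyePhantomSpec) -> None:
    r0, c0 = spec.iris_center
    margin = 2.0
    if (
        r0 - spec.iris_radius < margin
        or c0 - spec.iris_radius < margin
        or r0 + spec.iris_radius > spec.image_size - 1 - margin
        or c0 + spec.iris_radius > spec.image_size - 1 - margin
    ):
        raise GeometryError("iris circle not fully inside the frame")


def _add_noise(pixels: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    if sigma <= 0:
        return pixels
    rng = np.random.default_rng(seed)
    return pixels + rng.normal(0.0, sigma, size=pixels.shape).astype(np.float32)


def render_frontal(spec: EyePhantomSpec) -> Image2D:
    """Render the frontal view: dark iris disc + pupil on a light sclera.

    The strongest circular edge is the limbus at ``spec.iris_radius``.
    Edges are anti-aliased over one pixel so subpixel methods behave.
    """
    _check_frontal_geometry(spec)
    n = spec.image_size
    rr, cc = np.mgrid[0:n, 0:n].astype(np.float32)
    rho = np.hypot(rr - spec.iris_center[0], cc - spec.iris_center[1])

    def smooth_step(edge: float) -> np.ndarray:
        # 0 inside the disc of radius `edge`, 1 outside, 1-px linear ramp
        return np.clip(rho - edge + 0.5, 0.0, 1.0)

    img = _PUPIL + (_IRIS - _PUPIL) * smooth_step(_PUPIL_FRACTION * spec.iris_radius)
    img = img + (_SCLERA - _IRIS) * smooth_step(spec.iris_radius)
    img = _add_noise(img.astype(np.float32), spec.noise_sigma, spec.seed)
    return Image2D(img)


def render_lateral(spec: EyePhantomSpec) -> tuple[Image2D, LateralTruth]:
    """Render the lateral profile silhouette and its ground-truth landmarks.

    The head/eye body fills all columns up to the limbus chord; the cornea
    bulges rightward between the limbus rows.  Returns the image and the
    exact apex / chord-endpoint coordinates.
    """
    n = spec.image_size
    r0 = spec.iris_center[0]
    R, h = spec.iris_radius, float(spec.cornea_apex_height)
    chord = spec.chord_col
    if chord + h > n - 3:
        raise GeometryError("corneal apex would protrude outside the frame")
    if r0 - R < 2 or r0 + R > n - 3:
        raise GeometryError("limbus span does not fit inside the frame")

    rows = np.arange(n, dtype=np.float32)
    prof = spec.lateral_profile(rows, chord).astype(np.float32)
    cols = np.arange(n, dtype=np.float32)
    # anti-aliased boundary: 2-px intensity ramp across the silhouette edge,
    # wide enough that subpixel contour tracing is staircase-free even for
    # near-diagonal (45 degree) corneal flanks
    ramp = 2.0
    frac = np.clip((cols[None, :] - prof[:, None] + ramp / 2) / ramp, 0.0, 1.0)
    img = _BODY + (_BACKGROUND - _BODY) * frac
    img = _add_noise(img.astype(np.float32), spec.noise_sigma, spec.seed + 1)
    truth = LateralTruth(
        apex=(r0, chord + h),
        p2=(r0 - R, chord),
        p3=(r0 + R, chord),
        chord_col=chord,
        apex_height=h,
    )
    return Image2D(img), truth


def elevation_map(spec: EyePhantomSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Corneal elevation z(x, y) above the limbus plane, in pixels.

    ``x``/``y`` are offsets from the corneal axis (frontal iris center).
    Zero outside the limbus circle.
    """
    rho = np.hypot(x, y)
    R, h = spec.iris_radius, float(spec.cornea_apex_height)
    z = np.zeros_like(rho, dtype=np.float32)
    inside = rho <= R
    if spec.is_cone:
        z[inside] = h * (1.0 - rho[inside] / R)
    else:
        Rc = (R * R + h * h) / (2.0 * h) if h > 0 else np.inf
        if np.isfinite(Rc):
            z[inside] = np.sqrt(np.maximum(Rc * Rc - rho[inside] ** 2, 0.0)) - (Rc - h)
            z[inside] = np.maximum(z[inside], 0.0)
    return z


#: Reference elevation used to map height to grey level across the cohort,
#: as a multiple of the iris radius (tan 65 deg ~ 2.14 is the steepest cone).
_ELEVATION_REF = 2.2


def render_volume(spec: EyePhantomSpec, size: int = 72) -> Volume3D:
    """Rasterize the corneal surface as a voxel shell.

    The field of view spans 2.4 iris radii in x/y and the full elevation
    range in z, with isotropic voxels.  Shell intensity encodes elevation:
    dark grey = high elevation, light grey = flat (limbus plane).
    """
    R = spec.iris_radius
    a = 2.4 * R / size  # voxel edge, pixels
    centers = (np.arange(size, dtype=np.float32) - (size - 1) / 2.0) * a
    x, y = np.meshgrid(centers, centers, indexing="ij")
    z_surf = elevation_map(spec, x, y)  # (x, y)
    zc = np.arange(size, dtype=np.float32) * a  # z starts at the limbus plane
    # shell of ~1.5 voxel half-thickness around the surface
    dist = np.abs(zc[None, None, :] - z_surf[..., None])
    shell = dist <= 1.5 * a
    inside_disc = (np.hypot(x, y) <= R)[..., None]
    h_ref = _ELEVATION_REF * R
    intensity = 1.0 - 0.7 * np.clip(z_surf / h_ref, 0.0, 1.0)
    vox = np.where(shell & inside_disc, intensity[..., None], 0.0).astype(np.float32)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 2)
        vox = vox + rng.normal(0.0, spec.noise_sigma / 255.0, size=vox.shape).astype(
            np.float32
        )
    return Volume3D(vox, spacing=a)


def _validate_ranges(stage_ranges: dict[str, tuple[float, float]]) -> None:
    for stage, (lo, hi) in stage_ranges.items():
        if stage not in STAGES:
            raise ConfigurationError(f"unknown stage {stage!r} in stage ranges")
        if not (0.0 < lo <= hi < 90.0):
            raise ConfigurationError(f"invalid steepness range for {stage!r}")
        if stage == "mild" and hi >= 45.0:
            raise ConfigurationError("mild range straddles the 45 degree boundary")
        if stage == "moderate" and (lo < 45.0 or hi > 52.0):
            raise ConfigurationError("moderate range leaves the [45, 52] degree band")
        if stage == "severe" and lo <= 52.0:
            raise ConfigurationError("severe range straddles the 52 degree boundary")
        if stage == "normal" and hi >= 45.0:
            raise ConfigurationError("normal caps must stay below the mild threshold")
    spans = sorted(stage_ranges.values())
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        if hi1 >= lo2:
            raise ConfigurationError("stage steepness ranges overlap")


def generate_cohort(
    n_per_stage: int,
    seed: int,
    stage_params: dict[str, tuple[float, float]] | None = None,
    noise_sigma: float = 2.0,
    image_size: int = 256,
    volume_size: int = 72,
) -> list[PhantomCase]:
    """Generate a reproducible labeled cohort, ``n_per_stage`` cases per stage.

    Steepness is sampled uniformly inside each stage's range; iris radius and
    center are jittered so cases within a stage are not clones.  The stage
    label of every case agrees with the staging of its ground-truth steepness
    by construction (ranges are validated against the 45/52 degree
    thresholds).
    """
    if n_per_stage < 1:
        raise ConfigurationError("n_per_stage must be >= 1")
    ranges = dict(DEFAULT_STAGE_RANGES if stage_params is None else stage_params)
    _validate_ranges(ranges)
    root = np.random.SeedSequence(seed)
    cases: list[PhantomCase] = []
    for stage in STAGES:
        if stage not in ranges:
            raise ConfigurationError(f"missing steepness range for stage {stage!r}")
        lo, hi = ranges[stage]
        for i in range(n_per_stage):
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            case_seed = int(rng.integers(0, 2**31 - 1))
            steep = float(rng.uniform(lo, hi))
            radius = float(rng.uniform(0.15 * image_size, 0.19 * image_size))
            jitter = rng.uniform(-0.02 * image_size, 0.02 * image_size, size=2)
            center = (image_size / 2.0 + jitter[0], image_size / 2.0 + jitter[1])
            spec = EyePhantomSpec(
                image_size=image_size,
                iris_center=center,
                iris_radius=radius,
                steepness_angle_deg=steep,
                stage_label=stage,
                noise_sigma=noise_sigma,
                seed=case_seed,
            )
            frontal = render_frontal(spec)
            lateral, truth = render_lateral(spec)
            volume = render_volume(spec, size=volume_size)
            cases.append(
                PhantomCase(
                    case_id=f"{stage}_{i:03d}",
                    spec=spec,
                    frontal=frontal,
                    lateral=lateral,
                    lateral_truth=truth,
                    volume=volume,
                    stage=stage,
                )
            )
    return cases


def write_cohort(cases: list[PhantomCase], out_dir: str | Path) -> Path:
    """Write a cohort to disk: PNG views, NIfTI volumes, CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "case_id",
                "stage",
                "steepness_deg",
                "iris_radius",
                "iris_row",
                "iris_col",
                "apex_row",
                "apex_col",
                "frontal",
                "lateral",
                "volume",
            ]
        )
        for case in cases:
            f_name = f"{case.case_id}_frontal.png"
            l_name = f"{case.case_id}_lateral.png"
            v_name = f"{case.case_id}_volume.nii.gz"
            save_image(case.frontal, out / f_name)
            save_image(case.lateral, out / l_name)
            save_volume(case.volume, out / v_name)
            writer.writerow(
                [
                    case.case_id,
                    case.stage,
                    f"{case.spec.steepness_angle_deg:.4f}",
                    f"{case.spec.iris_radius:.4f}",
                    f"{case.spec.iris_center[0]:.4f}",
                    f"{case.spec.iris_center[1]:.4f}",
                    f"{case.lateral_truth.apex[0]:.4f}",
                    f"{case.lateral_truth.apex[1]:.4f}",
                    f_name,
                    l_name,
                    v_name,
                ]
            )
    return manifest
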