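"""End-to-end orchestration: images -> iris -> features -> depth -> 3D ->
curvature stage (and, optionally, CNN class).

Per case the pipeline

1. detects the iris circle in the frontal view (circular Hough transform);
2. extracts and matches scale-invariant keypoints across the two views
   (diagnostic; cases with few matches are flagged, not failed);
3. finds the lateral depth landmarks (apex, limbus chord endpoints) and the
   corneal depth;
4. estimates the orthogonal-view translation from the limbus landmark
   correspondences (top/bottom limbus and center seen in both views) — the
   keypoint matches can be used instead via ``use_sift_transform``;
5. optionally fuses the lateral depth profile, revolved around the corneal
   axis over the frontal iris disc, into a 3D volume;
6. measures the greatest tangent slope of the corneal contour, builds the
   apex displacement triangle, and grades the stage.

A cone is considered present when the corneal depth exceeds
``cone_depth_ratio`` times the iris radius; spherical (normal) corneas sit
well below that ratio, true cones well above it.

Batch runs never abort on a failing case: the result row records the failing
stage and the run continues.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import curvature as curv
from . import depth as depth_mod
from . import features as feat
from . import iris as iris_mod
from . import reconstruct as rec
from .errors import Kerato3dError
from .io import Image2D, Volume3D, canonicalize_lateral, load_image
from .phantom import PhantomCase
from .evaluation import ConfusionMatrix, confusion

logger = logging.getLogger("kerato3d")

__all__ = ["PipelineConfig", "CaseResult", "run_case", "run_cohort",
           "build_case_volume"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their defaults."""

    # iris detection
    radius_range: tuple[int, int] | None = None  # None: (size//10, size//4)
    edge_sigma: float = 2.0
    min_support: float = 0.25
    # keypoint matching
    ratio_threshold: float = 0.8
    min_matches: int = 4
    use_sift_transform: bool = False
    # staging
    cone_depth_ratio: float = 0.60
    profile_smooth_sigma: float = 0.0
    boundary_guard_deg: float = 1.0
    # reconstruction
    build_volume: bool = False
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    smoothing_sigma: float = 1.0
    # control flow
    cnn_gates_staging: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class CaseResult:
    """Everything one case produced, or the stage where it failed."""

    case_id: str
    iris: iris_mod.IrisCircle | None = None
    n_matches: int | None = None
    landmarks: depth_mod.DepthLandmarks | None = None
    transform: rec.OrthoTransform | None = None
    triangle: curv.CurvatureTriangle | None = None
    stage_geometric: curv.StageResult | None = None
    stage_cnn: str | None = None
    volume: Volume3D | None = None
    qc_flags: list[str] = field(default_factory=list)
    error: str | None = None
    failed_stage: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None

    def to_row(self) -> dict:
        row = {"case_id": self.case_id, "error": self.error or "",
               "failed_stage": self.failed_stage or "",
               "qc_flags": ";".join(self.qc_flags)}
        if self.iris is not None:
            row.update(iris_m=self.iris.m, iris_n=self.iris.n, iris_r=self.iris.r,
                       iris_votes=round(self.iris.votes, 6))
        if self.n_matches is not None:
            row["n_matches"] = self.n_matches
        if self.landmarks is not None:
            row["depth_px"] = round(self.landmarks.d, 4)
        if self.triangle is not None:
            row["theta_deg"] = round(self.triangle.theta, 4)
            row["angle_of_curvature_deg"] = round(self.triangle.angle_of_curvature, 4)
        if self.stage_geometric is not None:
            row["steepness_deg"] = round(self.stage_geometric.steepness_deg, 4)
            row["stage_geometric"] = self.stage_geometric.stage
        if self.stage_cnn is not None:
            row["stage_cnn"] = self.stage_cnn
        return row


def _landmark_correspondences(circle: iris_mod.IrisCircle,
                              lm: depth_mod.DepthLandmarks):
    """(x, y) = (col, row) pairs seen in both views: top/bottom limbus + center."""
    center, _, (top, bottom) = iris_mod.iris_landmarks(circle)
    frontal = np.array([[top[1], top[0]], [bottom[1], bottom[0]],
                        [center[1], center[0]]])
    lateral = np.array([[lm.p2[1], lm.p2[0]], [lm.p3[1], lm.p3[0]],
                        [lm.C[1], lm.C[0]]])
    return frontal, lateral


def build_case_volume(
    circle: iris_mod.IrisCircle,
    lm: depth_mod.DepthLandmarks,
    profile: tuple[np.ndarray, np.ndarray],
    t: rec.OrthoTransform,
    shape: tuple[int, int, int],
    smoothing_sigma: float,
    n_meridians: int = 24,
    n_radial: int = 12,
) -> Volume3D:
    """Revolve the lateral depth profile around the corneal axis and
    rasterize.

    The lateral contour constrains the vertical meridian; rotational symmetry
    of the cornea extends it over the frontal iris disc: at polar radius
    ``rho`` from the axis the elevation is the profile's depth at
    ``|row - apex_row| = rho``.
    """
    rows, cols = profile
    apex_row = lm.p1[0]
    radii = np.linspace(0.0, float(circle.r), n_radial)
    # average the two meridian halves for robustness to noise
    z_up = np.interp(apex_row - radii, rows, cols)
    z_dn = np.interp(apex_row + radii, rows, cols)
    z_of_rho = 0.5 * (z_up + z_dn)  # lateral columns (depth axis)
    angles = np.linspace(0.0, 2 * np.pi, n_meridians, endpoint=False)
    frontal_pts = []
    lateral_pts = []
    for rho, z in zip(radii, z_of_rho):
        for a in (angles if rho > 0 else angles[:1]):
            x1 = circle.m + rho * np.cos(a)
            y1 = circle.n + rho * np.sin(a)
            y2 = y1 - t.ty
            frontal_pts.append((x1, y1))
            lateral_pts.append((z, y2))
    fused = rec.fuse_points(np.array(frontal_pts), np.array(lateral_pts), t)
    return rec.rasterize_volume(fused, shape, smoothing_sigma=smoothing_sigma)


def run_case(
    frontal: Image2D,
    lateral: Image2D,
    config: PipelineConfig | None = None,
    case_id: str = "case",
    model=None,
    intermediates_dir: str | Path | None = None,
) -> CaseResult:
    """Run the full geometric pipeline on one image pair.

    Any stage failure is captured in the result (``error`` +
    ``failed_stage``); nothing is raised.  With ``intermediates_dir`` set,
    the per-stage outputs (iris circle, landmarks, transform, triangle,
    stage; the volume as NIfTI when built) are persisted there.
    """
    import time as _time

    cfg = config or PipelineConfig()
    result = CaseResult(case_id=case_id)
    stage = "input"
    t_stage = _time.perf_counter()

    def tick(next_stage: str) -> str:
        nonlocal t_stage
        now = _time.perf_counter()
        logger.info("case %s: stage %s done in %.3fs", case_id, stage, now - t_stage)
        t_stage = now
        return next_stage

    try:
        lateral = canonicalize_lateral(lateral)

        stage = tick("iris")
        size = min(frontal.shape)
        rng_px = cfg.radius_range or (max(8, size // 10), size // 4)
        logger.info("case %s: iris radius range %s, edge sigma %.1f",
                    case_id, rng_px, cfg.edge_sigma)
        circle = iris_mod.detect_iris(
            frontal, rng_px, edge_sigma=cfg.edge_sigma, min_support=cfg.min_support
        )
        result.iris = circle

        stage = tick("features")
        kp_f = feat.extract_keypoints(frontal)
        kp_l = feat.extract_keypoints(lateral)
        matches = feat.match_keypoints(kp_f, kp_l, cfg.ratio_threshold)
        result.n_matches = len(matches)
        if len(matches) < cfg.min_matches:
            result.qc_flags.append("low_matches")

        stage = tick("depth")
        lm = depth_mod.find_depth_landmarks(lateral, circle)
        result.landmarks = lm

        stage = tick("reconstruct")
        if cfg.use_sift_transform and len(matches) >= cfg.min_matches:
            pa, pb = matches.positions(kp_f, kp_l)
            t = rec.estimate_transform(pa[:, ::-1], pb[:, ::-1])  # (row,col)->(x,y)
        else:
            if cfg.use_sift_transform:
                result.qc_flags.append("landmark_fallback")
            f_pts, l_pts = _landmark_correspondences(circle, lm)
            t = rec.estimate_transform(f_pts, l_pts)
        result.transform = t

        profile = depth_mod.rightmost_profile(lateral)
        if cfg.build_volume:
            result.volume = build_case_volume(
                circle, lm, profile, t, cfg.volume_shape, cfg.smoothing_sigma
            )

        stage = tick("classifier")
        if model is not None:
            from .classifier import predict, preprocess_volume

            vol = result.volume
            if vol is None:
                vol = build_case_volume(
                    circle, lm, profile, t, cfg.volume_shape, cfg.smoothing_sigma
                )
            _, label = predict(model, preprocess_volume(vol, model.cfg))
            result.stage_cnn = label

        stage = tick("curvature")
        if cfg.cnn_gates_staging and result.stage_cnn == "normal":
            result.stage_geometric = curv.StageResult(steepness_deg=0.0, stage="normal")
        else:
            steep = curv.steepness_from_profile(
                profile[0], profile[1],
                row_lo=lm.p2[0], row_hi=lm.p3[0],
                smooth_sigma=cfg.profile_smooth_sigma,
            )
            cone = lm.d > cfg.cone_depth_ratio * circle.r
            result.triangle = curv.triangle_from_landmarks(lm)
            result.stage_geometric = curv.grade_stage(steep, cone)
            if (
                abs(steep - curv.MILD_MAX_DEG) < cfg.boundary_guard_deg
                or abs(steep - curv.MODERATE_MAX_DEG) < cfg.boundary_guard_deg
            ):
                result.qc_flags.append("boundary_adjacent")
    except (Kerato3dError, OSError, ValueError) as exc:
        result.error = f"{type(exc).__name__}: {exc}"
        result.failed_stage = stage
        logger.warning("case %s failed at %s: %s", case_id, stage, exc)
    if intermediates_dir is not None:
        _persist_intermediates(result, Path(intermediates_dir))
    return result


def _persist_intermediates(result: CaseResult, out_dir: Path) -> None:
    import json

    from .io import save_volume

    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{result.case_id}.json").write_text(
        json.dumps(result.to_row(), indent=2, default=str)
    )
    if result.volume is not None:
        save_volume(result.volume, out_dir / f"{result.case_id}_volume.nii.gz")


def run_cohort(
    cases,
    config: PipelineConfig | None = None,
    model=None,
    intermediates_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, ConfusionMatrix | None]:
    """Run a batch of cases and tabulate results.

    ``cases`` is either a list of :class:`~kerato3d.phantom.PhantomCase`
    objects or a manifest CSV path with columns ``case_id, frontal, lateral``
    (+ optional ``stage`` ground truth, paths relative to the manifest).
    Failing or unreadable cases produce error rows; the run continues.
    Returns the per-case results table and, when ground truth is available, a
    confusion matrix of geometric stages over the successful cases.
    """
    cfg = config or PipelineConfig()
    rows: list[dict] = []
    truths: list[str] = []
    preds: list[str] = []

    def handle(case_id: str, frontal: Image2D, lateral: Image2D, truth: str | None):
        res = run_case(frontal, lateral, cfg, case_id=case_id, model=model,
                       intermediates_dir=intermediates_dir)
        row = res.to_row()
        if truth is not None:
            row["stage_true"] = truth
        rows.append(row)
        if truth is not None and res.ok and res.stage_geometric is not None:
            truths.append(truth)
            preds.append(res.stage_geometric.stage)

    if isinstance(cases, (str, Path)):
        manifest = Path(cases)
        table = pd.read_csv(manifest)
        for rec_ in table.itertuples(index=False):
            truth = getattr(rec_, "stage", None)
            try:
                frontal = load_image(manifest.parent / rec_.frontal)
                lateral = load_image(manifest.parent / rec_.lateral)
            except Exception as exc:  # unreadable/corrupt files of any flavor
                rows.append({"case_id": rec_.case_id,
                             "error": f"{type(exc).__name__}: {exc}",
                             "failed_stage": "input", "qc_flags": "",
                             **({"stage_true": truth} if truth is not None else {})})
                logger.warning("case %s unreadable: %s", rec_.case_id, exc)
                continue
            handle(str(rec_.case_id), frontal, lateral, truth)
    else:
        for case in cases:
            if isinstance(case, PhantomCase):
                handle(case.case_id, case.frontal, case.lateral, case.stage)
            else:
                case_id, frontal, lateral = case[:3]
                truth = case[3] if len(case) > 3 else None
                handle(case_id, frontal, lateral, truth)

    df = pd.DataFrame(rows)
    cm = confusion(truths, preds) if truths else None
    return df, cm
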