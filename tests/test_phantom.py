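"""Phantom generator: geometry, ground truth, determinism, cohort bookkeeping."""

import numpy as np
import pytest

from kerato3d.curvature import steepness_from_profile
from kerato3d.depth import rightmost_profile
from kerato3d.errors import ConfigurationError, GeometryError
from kerato3d.io import load_image
from kerato3d.phantom import (
    DEFAULT_STAGE_RANGES,
    STAGES,
    EyePhantomSpec,
    generate_cohort,
    render_frontal,
    render_lateral,
    render_volume,
    stage_for_steepness,
    write_cohort,
)


class TestSpecValidation:
    def test_apex_height_derived_from_steepness(self):
        spec = EyePhantomSpec(steepness_angle_deg=45.0, stage_label="moderate")
        assert spec.cornea_apex_height == pytest.approx(
            spec.iris_radius * np.tan(np.deg2rad(45.0))
        )
        cap = EyePhantomSpec(steepness_angle_deg=30.0, stage_label="normal")
        assert cap.cornea_apex_height == pytest.approx(
            cap.iris_radius * np.tan(np.deg2rad(15.0))
        )

    def test_inconsistent_label_rejected(self):
        with pytest.raises(ConfigurationError):
            EyePhantomSpec(steepness_angle_deg=60.0, stage_label="mild")
        with pytest.raises(ConfigurationError):
            EyePhantomSpec(steepness_angle_deg=50.0, stage_label="normal")

    def test_bad_geometry_rejected(self):
        with pytest.raises(GeometryError):
            EyePhantomSpec(iris_radius=-1.0)
        with pytest.raises(GeometryError):
            EyePhantomSpec(steepness_angle_deg=95.0, stage_label="severe")
        with pytest.raises(GeometryError):
            EyePhantomSpec(
                steepness_angle_deg=43.0, stage_label="mild", cornea_apex_height=10.0
            )


class TestFrontal:
    def test_iris_disc_intensities(self, mild_spec):
        img = render_frontal(mild_spec).pixels
        r0, c0 = mild_spec.iris_center
        r = mild_spec.iris_radius
        assert img[int(r0), int(c0)] < 50  # pupil
        assert img[int(r0), int(c0 + 0.7 * r)] == pytest.approx(90, abs=5)  # iris
        assert img[int(r0), int(c0 + 1.5 * r)] == pytest.approx(200, abs=5)  # sclera

    def test_deterministic_given_seed(self):
        spec = EyePhantomSpec(noise_sigma=4.0, seed=99)
        a = render_frontal(spec).pixels
        b = render_frontal(spec).pixels
        np.testing.assert_array_equal(a, b)

    def test_noise_free_ignores_seed(self, normal_spec):
        a = render_frontal(normal_spec).pixels
        b = render_frontal(
            EyePhantomSpec(steepness_angle_deg=35.0, stage_label="normal", seed=123)
        ).pixels
        np.testing.assert_array_equal(a, b)

    def test_iris_near_border_rejected(self):
        spec = EyePhantomSpec(iris_center=(30.0, 128.0))
        with pytest.raises(GeometryError):
            render_frontal(spec)


class TestLateral:
    def test_ground_truth_landmarks(self, mild_spec):
        _, truth = render_lateral(mild_spec)
        r0 = mild_spec.iris_center[0]
        R = mild_spec.iris_radius
        assert truth.p2 == (r0 - R, truth.chord_col)
        assert truth.p3 == (r0 + R, truth.chord_col)
        # apex lies apex_height beyond the chord midpoint
        assert truth.apex[0] == r0
        assert truth.apex[1] - truth.chord_col == pytest.approx(truth.apex_height)

    @pytest.mark.parametrize(
        "stage,steep",
        [("normal", 30.0), ("normal", 40.0), ("mild", 41.0), ("mild", 44.0),
         ("moderate", 46.0), ("moderate", 51.0), ("severe", 53.0), ("severe", 60.0),
         ("severe", 65.0)],
    )
    def test_steepness_recoverable_from_rendered_contour(self, stage, steep):
        """Ground-truth steepness recomputed from the rendered noise-free
        contour agrees with the spec angle within 1 degree."""
        spec = EyePhantomSpec(
            steepness_angle_deg=steep, stage_label=stage, noise_sigma=0.0
        )
        img, truth = render_lateral(spec)
        rows, cols = rightmost_profile(img)
        measured = steepness_from_profile(rows, cols, truth.p2[0], truth.p3[0])
        assert measured == pytest.approx(steep, abs=1.0)

    def test_cone_max_tangent_slope_matches_steepness(self):
        """Numeric differentiation of the rendered 60-degree cone contour."""
        spec = EyePhantomSpec(steepness_angle_deg=60.0, stage_label="severe",
                              noise_sigma=0.0)
        img, truth = render_lateral(spec)
        rows, cols = rightmost_profile(img)
        sel = (rows > truth.p2[0] + 2) & (rows < truth.p3[0] - 2)
        slopes = np.abs(np.gradient(cols[sel], rows[sel]))
        assert np.degrees(np.arctan(slopes.max())) == pytest.approx(60.0, abs=1.0)

    def test_apex_outside_frame_rejected(self):
        spec = EyePhantomSpec(
            image_size=128,
            iris_center=(64.0, 64.0),
            iris_radius=24.0,
            steepness_angle_deg=65.0,
            stage_label="severe",
        )
        # 30 * tan(65) ~ 64 px protrusion from column 40 overflows a 100-px frame
        spec2 = EyePhantomSpec(
            image_size=100, iris_center=(50.0, 50.0), iris_radius=30.0,
            steepness_angle_deg=65.0, stage_label="severe",
        )
        render_lateral(spec)  # fits
        with pytest.raises(GeometryError):
            render_lateral(spec2)

    def test_noise_free_render_ignores_seed(self, normal_spec):
        a, _ = render_lateral(normal_spec)
        b, _ = render_lateral(
            EyePhantomSpec(steepness_angle_deg=35.0, stage_label="normal", seed=77)
        )
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestVolume:
    def test_shell_darkens_with_elevation(self):
        cone = EyePhantomSpec(steepness_angle_deg=60.0, stage_label="severe")
        vol = render_volume(cone, size=64).voxels
        nz = vol > 0
        assert nz.any()
        zidx = np.nonzero(nz)[2]
        low = vol[:, :, : max(2, zidx.min() + 2)]
        high = vol[:, :, zidx.max() - 1 :]
        assert low[low > 0].mean() > high[high > 0].mean()

    def test_apex_column_reaches_highest_z(self):
        cone = EyePhantomSpec(steepness_angle_deg=55.0, stage_label="severe")
        vol = render_volume(cone, size=64).voxels
        occ = vol > 0
        zmax_per_xy = np.where(occ.any(axis=2), occ.shape[2] - 1
                               - np.argmax(occ[:, :, ::-1], axis=2), -1)
        peak = np.unravel_index(np.argmax(zmax_per_xy), zmax_per_xy.shape)
        center = (np.array(vol.shape[:2]) - 1) / 2
        assert np.hypot(peak[0] - center[0], peak[1] - center[1]) <= 2.0


class TestCohort:
    def test_counts_and_labels(self, small_cohort):
        assert len(small_cohort) == 8
        labels = sorted(c.stage for c in small_cohort)
        assert labels == sorted(list(STAGES) * 2)
        for case in small_cohort:
            assert case.stage == stage_for_steepness(
                case.spec.steepness_angle_deg, case.spec.is_cone
            )

    def test_default_mild_below_45(self):
        cases = generate_cohort(3, seed=1, noise_sigma=0.0)
        for case in cases:
            if case.stage == "mild":
                assert case.spec.steepness_angle_deg < 45.0

    def test_same_seed_identical_cohorts(self):
        a = generate_cohort(1, seed=7, image_size=128, volume_size=32)
        b = generate_cohort(1, seed=7, image_size=128, volume_size=32)
        for ca, cb in zip(a, b):
            assert ca.spec == cb.spec
            np.testing.assert_array_equal(ca.frontal.pixels, cb.frontal.pixels)
            np.testing.assert_array_equal(ca.volume.voxels, cb.volume.voxels)

    def test_boundary_straddling_ranges_rejected(self):
        bad = dict(DEFAULT_STAGE_RANGES, mild=(41.0, 46.0))
        with pytest.raises(ConfigurationError):
            generate_cohort(1, seed=0, stage_params=bad)
        overlapping = dict(DEFAULT_STAGE_RANGES, normal=(30.0, 42.0))
        with pytest.raises(ConfigurationError):
            generate_cohort(1, seed=0, stage_params=overlapping)

    def test_write_cohort_roundtrip(self, small_cohort, tmp_path):
        manifest = write_cohort(small_cohort[:2], tmp_path)
        assert manifest.exists()
        import pandas as pd

        table = pd.read_csv(manifest)
        assert len(table) == 2
        img = load_image(tmp_path / table.iloc[0]["frontal"])
        np.testing.assert_allclose(
            img.pixels, np.clip(np.rint(small_cohort[0].frontal.pixels), 0, 255),
            atol=0.5,
        )
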