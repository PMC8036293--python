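"""Volumetric CNN: shape arithmetic, optimization sanity, preprocessing.

Unit tests run a narrow configuration (small channel counts, small cubes) so
the whole file stays fast; the full-width network is exercised by the
acceptance suite.
"""

import numpy as np
import pytest

from kerato3d.classifier import (
    CnnConfig,
    build_model,
    load_model,
    predict,
    preprocess_volume,
    save_model,
    train,
)
from kerato3d.errors import ConfigurationError, Kerato3dError
from kerato3d.io import Volume3D
from kerato3d.phantom import EyePhantomSpec, render_volume

SMALL = dict(input_edge=48, conv_channels=(4, 8, 8, 16), fc_width=32,
             accumulation_chunk=8)


def tiny_cohort(n_per_class: int, seed: int, edge: int = 32):
    """Preprocessed phantom volumes, n per class."""
    cfg = CnnConfig(**SMALL)
    rng = np.random.default_rng(seed)
    vols, labels = [], []
    steep = {"normal": (30, 40), "mild": (41, 44), "moderate": (46, 51),
             "severe": (53, 65)}
    for stage, (lo, hi) in steep.items():
        for _ in range(n_per_class):
            spec = EyePhantomSpec(
                steepness_angle_deg=float(rng.uniform(lo, hi)), stage_label=stage,
                iris_radius=float(rng.uniform(40, 48)),
            )
            vols.append(preprocess_volume(render_volume(spec, size=48), cfg))
            labels.append(stage)
    return vols, labels, cfg


class TestConfig:
    def test_layer_edges_hand_computed(self):
        assert CnnConfig(input_edge=64).layer_edges() == [31, 14, 6, 2]
        assert CnnConfig(input_edge=48).layer_edges() == [23, 10, 4, 1]

    def test_input_edge_8_collapses(self):
        with pytest.raises(ConfigurationError):
            CnnConfig(input_edge=8)

    def test_wrong_channel_count(self):
        with pytest.raises(ConfigurationError):
            CnnConfig(conv_channels=(96, 128, 256))


class TestModel:
    def test_untrained_softmax_sums_to_one(self):
        cfg = CnnConfig(**SMALL)
        model = build_model(cfg)
        x = np.random.default_rng(0).uniform(0, 1, (3, 48, 48, 48)).astype(np.float32)
        probs = model.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape == (3, 4)

    def test_same_seed_identical_initial_parameters(self):
        cfg = CnnConfig(**SMALL, seed=5)
        a = build_model(cfg).net.parameters()
        b = build_model(cfg).net.parameters()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_parameter_count_is_reported(self):
        model = build_model(CnnConfig(**SMALL))
        assert model.n_parameters > 0
        # conv1: 4 kernels * 1 channel * 27 + 4 biases
        assert model.net.layers[0].params["W"].size == 4 * 27

    def test_wrong_input_shape_rejected(self):
        model = build_model(CnnConfig(**SMALL))
        with pytest.raises(Kerato3dError):
            model.logits(np.zeros((1, 16, 16, 16), dtype=np.float32))


class TestTraining:
    def test_zero_learning_rate_changes_nothing(self):
        vols, labels, _ = tiny_cohort(2, seed=1)
        cfg = CnnConfig(**SMALL, learning_rate=0.0, epochs=3,
                        early_stop_accuracy=None, calibrate_init=False)
        model = build_model(cfg)
        before = {k: v.copy() for k, v in model.net.parameters().items()}
        train(model, vols, labels, cfg)
        after = model.net.parameters()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
        losses = model.history["loss"]
        assert max(losses) - min(losses) < 1e-6

    def test_loss_non_increasing_on_memorization_task(self):
        vols, labels, _ = tiny_cohort(2, seed=2)  # 8 samples, two per class
        cfg = CnnConfig(**SMALL, learning_rate=0.002, epochs=12,
                        early_stop_accuracy=None)
        model = build_model(cfg)
        train(model, vols, labels, cfg)
        losses = np.array(model.history["loss"])
        assert np.all(np.diff(losses) <= 1e-6)

    def test_same_seed_identical_trajectory(self):
        vols, labels, _ = tiny_cohort(2, seed=3)
        cfg = CnnConfig(**SMALL, learning_rate=0.01, epochs=3,
                        early_stop_accuracy=None, seed=11)
        h1 = train(build_model(cfg), vols, labels, cfg).history
        h2 = train(build_model(cfg), vols, labels, cfg).history
        assert h1["loss"] == h2["loss"]
        assert h1["accuracy"] == h2["accuracy"]

    def test_missing_class_rejected(self):
        vols, labels, cfg = tiny_cohort(1, seed=4)
        keep = [i for i, lb in enumerate(labels) if lb != "severe"]
        with pytest.raises(Kerato3dError):
            train(build_model(CnnConfig(**SMALL)),
                  [vols[i] for i in keep] + [vols[keep[0]]] * 5,
                  [labels[i] for i in keep] + [labels[keep[0]]] * 5,
                  CnnConfig(**SMALL, epochs=1))

    def test_small_net_learns_separable_classes(self):
        vols, labels, _ = tiny_cohort(3, seed=5)
        cfg = CnnConfig(**SMALL, learning_rate=0.01, epochs=30, seed=1)
        model = train(build_model(cfg), vols, labels, cfg)
        # plain fixed-rate SGD oscillates near the optimum on a tiny batch,
        # so the best epoch (where early stopping fires) is the claim
        assert max(model.history["accuracy"]) >= 0.9

    def test_prediction_deterministic(self):
        vols, labels, cfg = tiny_cohort(2, seed=6)
        model = build_model(CnnConfig(**SMALL))
        p1, l1 = predict(model, vols[0])
        p2, l2 = predict(model, vols[0])
        np.testing.assert_array_equal(p1, p2)
        assert l1 == l2
        assert p1.sum() == pytest.approx(1.0, abs=1e-6)


class TestPreprocess:
    def test_output_shape_contract(self):
        cfg = CnnConfig(**SMALL)
        v = render_volume(EyePhantomSpec(), size=50)
        out = preprocess_volume(v, cfg)
        assert out.shape == (48, 48, 48)
        assert out.voxels.min() >= 0.0 and out.voxels.max() <= 1.0

    def test_constant_volume_passes_through(self):
        cfg = CnnConfig(**SMALL)
        v = Volume3D(np.full((20, 20, 20), 0.7, dtype=np.float32))
        out = preprocess_volume(v, cfg)
        np.testing.assert_allclose(out.voxels, 0.7, atol=1e-5)

    def test_roi_retains_surface_intensity(self):
        v = render_volume(
            EyePhantomSpec(steepness_angle_deg=50.0, stage_label="moderate"), size=64
        )
        vox = v.voxels
        mask = vox > 0.05 * vox.max()
        # the crop preprocess_volume uses is the padded bounding box of mask
        idx = [np.nonzero(mask.any(axis=tuple(a for a in range(3) if a != ax)))[0]
               for ax in range(3)]
        crop = vox[idx[0][0]: idx[0][-1] + 1,
                   idx[1][0]: idx[1][-1] + 1,
                   idx[2][0]: idx[2][-1] + 1]
        assert crop.sum() >= 0.99 * vox.sum()

    def test_empty_volume_rejected(self):
        with pytest.raises(Kerato3dError):
            preprocess_volume(Volume3D(np.zeros((0, 0, 0))), CnnConfig(**SMALL))


class TestPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        vols, labels, _ = tiny_cohort(2, seed=7)
        cfg = CnnConfig(**SMALL, epochs=1)
        model = train(build_model(cfg), vols, labels, cfg)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        p_orig, l_orig = predict(model, vols[0])
        p_load, l_load = predict(loaded, vols[0])
        np.testing.assert_allclose(p_orig, p_load, atol=1e-7)
        assert l_orig == l_load
        assert loaded.history["loss"] == model.history["loss"]
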