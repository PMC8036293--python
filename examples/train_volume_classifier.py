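"""Train the 3D CNN on a small phantom cohort and classify held-out volumes.

Uses a narrow configuration (small channel counts, 48-cube inputs) so the
example runs in about a minute on one CPU; the full-width network
(96/128/256/512 kernels, 64-cube inputs) trains the same way, just slower.
"""

from kerato3d import (CnnConfig, build_model, generate_cohort, predict,
                      preprocess_volume, train)

cfg = CnnConfig(input_edge=48, conv_channels=(8, 16, 16, 32), fc_width=64,
                seed=11)
cohort = generate_cohort(n_per_stage=4, seed=2, noise_sigma=0.0, volume_size=48)
volumes = [preprocess_volume(c.volume, cfg) for c in cohort]
labels = [c.stage for c in cohort]

model = train(build_model(cfg), volumes, labels, cfg)
best_ep = model.history["best_epoch"][0] + 1
print(f"{model.n_parameters} parameters, trained {len(model.history['loss'])} epochs")
print(f"returned checkpoint: epoch {best_ep}, "
      f"training accuracy {model.history['best_accuracy'][0]:.2f}")

held_out = generate_cohort(n_per_stage=1, seed=99, noise_sigma=0.0, volume_size=48)
print("\nheld-out predictions:")
for case in held_out:
    probs, label = predict(model, preprocess_volume(case.volume, cfg))
    status = "ok " if label == case.stage else "MISS"
    print(f"  {status} true={case.stage:9s} predicted={label:9s} "
          f"p={probs.max():.2f}")
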