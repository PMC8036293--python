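"""Stage a single case from its two views, step by step.

Runs the full geometric chain on one severe-keratoconus phantom: iris
detection (circular Hough transform), lateral depth landmarks, the apex
displacement triangle, tangent-slope steepness, and the graded stage.
"""

from kerato3d import EyePhantomSpec, render_frontal, render_lateral, run_case

spec = EyePhantomSpec(steepness_angle_deg=58.0, stage_label="severe", noise_sigma=2.0,
                      seed=3)
frontal = render_frontal(spec)
lateral, truth = render_lateral(spec)

result = run_case(frontal, lateral, case_id="example_severe")
assert result.ok, result.error

print(f"iris: center=({result.iris.m}, {result.iris.n}) px, radius={result.iris.r} px")
lm = result.landmarks
print(f"depth landmarks: apex={tuple(round(v, 1) for v in lm.p1)}, "
      f"corneal depth d={lm.d:.1f} px (true apex height {truth.apex_height:.1f} px)")
tri = result.triangle
print(f"apex triangle: theta={tri.theta:.1f} deg, "
      f"angle of curvature={tri.angle_of_curvature:.1f} deg")
print(f"steepness={result.stage_geometric.steepness_deg:.1f} deg "
      f"(ground truth {spec.steepness_angle_deg} deg)")
print(f"stage: {result.stage_geometric.stage}  (thresholds: <45 mild, 45-52 moderate, "
      f">52 severe)")
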