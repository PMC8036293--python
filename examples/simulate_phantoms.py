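"""Generate a small labeled phantom cohort and write it to disk.

Each case is a synthetic eye with known geometry: a frontal view (iris disc),
a lateral profile (spherical cap for normal corneas, cone for keratoconus),
and a matching 3D corneal volume.  The manifest CSV records the ground truth
(stage, steepness angle, iris radius, apex position) for every case.
"""

from kerato3d import generate_cohort, write_cohort

cases = generate_cohort(n_per_stage=2, seed=42, noise_sigma=2.0)
manifest = write_cohort(cases, "scratch/phantom_cohort")

print(f"wrote {len(cases)} cases to scratch/phantom_cohort")
for case in cases:
    spec = case.spec
    print(
        f"  {case.case_id:14s} stage={case.stage:9s} "
        f"steepness={spec.steepness_angle_deg:5.1f} deg  "
        f"iris r={spec.iris_radius:4.1f} px  apex height={spec.cornea_apex_height:5.1f} px"
    )
print(f"manifest: {manifest}")
print("Steepness is the greatest angle between the corneal surface tangent")
print("and the limbus plane; it fully determines the severity stage.")
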