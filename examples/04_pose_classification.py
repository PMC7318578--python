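"""Classify catalytically active substrate poses in trajectory frames.

Generates a synthetic trajectory with one aromatic and one aliphatic site
of metabolism at known active fractions, classifies every frame with the
distance/angle criteria (C_SOM–O_ferryl < 0.35 nm with the hydrogen-
interposition angle exclusion for aromatic sites; H_SOM–O_ferryl < 0.35 nm
with the 110–130° H–O–Fe window for aliphatic sites), and prints the
per-SOM percentages next to the construction truth.
"""

import numpy as np

from p450select import classify_frame, fraction_report, gen_pose_trajectory
from p450select.synth import SyntheticPoseConfig

cfg = SyntheticPoseConfig(
    n_frames=500,
    target_fraction={"arom": 66.1, "aliph": 29.0},
    seed=11,
)
frames, labels = gen_pose_trajectory(cfg)
report = fraction_report({"sim-A": frames}, cfg.soms, cfg.criteria)

print(report.rows.to_string(index=False))
print()
for som in cfg.soms:
    truth = 100.0 * labels[som.label].mean()
    print(f"{som.label}: constructed {truth:.1f}% active "
          f"({som.kind} criteria) — classifier agrees frame-by-frame: "
          f"{all(classify_frame(f, som, cfg.criteria) == l for f, l in zip(frames, labels[som.label]))}")
print()
print("On real MD output these percentages are the structural counterpart of")
print("the collision-efficiency intercepts: a SOM that satisfies the")
print("transition-state geometry more often has a higher ln A.")
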