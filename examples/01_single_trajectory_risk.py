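"""Risk scoring of a single trajectory against a parallel vessel.

Builds a capped-cylinder vessel (radius 1 mm) running parallel to a 60 mm
trajectory at several surface distances and prints the normalised risk
score next to its closed-form value R = (d_risk - d) / (d_risk - d_safety).
A distance below the 3 mm safety margin saturates the score to 1; a
distance beyond the 10 mm risk zone scores 0.
"""

import numpy as np

import seegplan as sp

cfg = sp.PlanningConfig()
entry = np.array([0.0, 0.0, 0.0])
target = np.array([60.0, 0.0, 0.0])

print("surface distance -> risk score (closed form)")
for d in (2.0, 3.0, 5.0, 7.0, 10.0, 15.0):
    curve = np.linspace([-20.0, d + 1.0, 0.0], [80.0, d + 1.0, 0.0], 10)
    vessel = sp.build_bvh(sp.make_tube(curve, 1.0, sides=64, name="vessel"))
    profile = sp.risk_profile(entry, target, [vessel], cfg)
    R = sp.risk_score(profile, cfg)
    if profile.safety_violated:
        expected = 1.0
        note = "safety margin violated"
    else:
        expected = float(np.clip((cfg.d_risk - d) / (cfg.d_risk - cfg.d_safety), 0, 1))
        note = ""
    print(f"  {d:5.1f} mm -> R = {R:.4f}  (expected {expected:.4f})  {note}")

print()
print("The score integrates vessel proximity along the whole trajectory,")
print("normalised so 0 means 'never nearer than 10 mm' and 1 means")
print("'came within 3 mm of a vessel somewhere'.")
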