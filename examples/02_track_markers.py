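"""Track two tools with the simulated stereo tracker and identify them.

Registers two Xpoint marker templates in a run-time database, observes
them through the stereo rig with realistic pixel noise, and lets the
tracker identify which tool produced each observation from the rigid-fit
residual alone.
"""

import numpy as np

from scopesight import (
    SENSOR,
    RigidTransform,
    TemplateDatabase,
    default_rig,
    identify_template,
    observe_marker,
)

rig = default_rig()  # 120 mm baseline, converged 10 deg, f = 1000 px

db = TemplateDatabase()
db.add("elbow_base", np.array(
    [[-35.0, -35.0, 0.0], [35.0, -35.0, 0.0], [35.0, 35.0, 0.0], [-35.0, 35.0, 0.0], [0.0, 0.0, 17.0]]
))
db.add("scope_head", np.array(
    [[-25.0, -25.0, 0.0], [25.0, -25.0, 0.0], [25.0, 25.0, 0.0], [-25.0, 25.0, 0.0], [0.0, 0.0, 12.0]]
))

poses = {
    "elbow_base": RigidTransform(np.eye(3), np.array([-80.0, 0.0, 520.0]), "elbow_base", SENSOR),
    "scope_head": RigidTransform(np.eye(3), np.array([90.0, 20.0, 480.0]), "scope_head", SENSOR),
}

print(f"database: {db.names()}\n")
for true_name, pose in poses.items():
    obs = observe_marker(rig, db[true_name], pose, noise_sigma_px=0.2, seed=42)
    name, tracked = identify_template(db, obs, max_residual_mm=2.0)
    err = np.linalg.norm(tracked.transform.translation - pose.translation)
    print(
        f"observed {true_name!r} -> identified {name!r}, "
        f"fit residual {tracked.rms_residual_mm:.3f} mm, "
        f"position error {err:.3f} mm"
    )

print(
    "\nThe residual of the rigid fit acts as the identity check: the right "
    "template fits to within the triangulation noise, a wrong one cannot."
)
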