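"""Run the target-registration-error protocol across cylinder angles.

A 2 mm circular model is registered to coincide with a checkerboard
intersection 20 mm from the scope tip; each trial pushes noisy tracker
observations through the whole pipeline and measures how far the overlaid
circle centre lands from the true intersection, in mm on the object plane.
"""

from scopesight import TREProtocol, run_tre_protocol, summarize

# one bench sweep: a single reading per angle, like reading the display once
sweep = run_tre_protocol(TREProtocol(noise_sigma_px=0.2, repetitions=1, seed=1))
print("single sweep (one reading per angle):")
for _, row in sweep.table.iterrows():
    print(f"  theta {row.angle_deg:+6.1f} deg: error {row.error_mm:.3f} mm")

# Monte-Carlo version: 100 repetitions per angle for stable statistics
result = run_tre_protocol(TREProtocol(noise_sigma_px=0.2, repetitions=100, seed=1))
print("\nMonte-Carlo protocol (9 angles x 100 repetitions):")
print(summarize(result))
print(
    "\nWith zero tracker noise this error is numerically zero at every "
    "angle; the numbers above are what 0.2 px of Xpoint noise propagated "
    "through pose estimation, angle estimation, chaining and distortion "
    "costs on the object plane."
)
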