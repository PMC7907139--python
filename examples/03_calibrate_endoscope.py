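"""Calibrate the arthroscope camera from synthetic checkerboard views.

Renders ten views of a planar checkerboard through a known camera with
barrel distortion, adds realistic corner-detection noise, and recovers the
intrinsics and Brown-Conrady distortion coefficients by homography
initialization plus joint nonlinear refinement.
"""

import numpy as np

from scopesight import CameraIntrinsics, DistortionModel
from scopesight.calibration import calibrate, synthetic_checkerboard_views

true_intr = CameraIntrinsics(fx=600.0, fy=605.0, cx=315.0, cy=245.0, width=640, height=480)
true_dist = DistortionModel(k1=-0.22, k2=0.04)

views, _ = synthetic_checkerboard_views(
    true_intr, true_dist, n_views=10, noise_sigma_px=0.2,
    rng=np.random.default_rng(0),
)
cal = calibrate(views, image_size=(640, 480))

print("        true     estimated")
print(f"fx   {true_intr.fx:8.2f}  {cal.intrinsics.fx:8.2f}")
print(f"fy   {true_intr.fy:8.2f}  {cal.intrinsics.fy:8.2f}")
print(f"cx   {true_intr.cx:8.2f}  {cal.intrinsics.cx:8.2f}")
print(f"cy   {true_intr.cy:8.2f}  {cal.intrinsics.cy:8.2f}")
print(f"k1   {true_dist.k1:8.4f}  {cal.distortion.k1:8.4f}")
print(f"k2   {true_dist.k2:8.4f}  {cal.distortion.k2:8.4f}")
print(f"\nrms reprojection error: {cal.rms_px:.3f} px "
      f"(corner noise was 0.2 px -> the fit sits at the noise floor)")
print(
    "The recovered distortion model is what the overlay renderer applies "
    "forward so computer-graphics geometry matches the distorted video."
)
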