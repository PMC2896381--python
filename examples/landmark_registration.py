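"""Landmark-based rigid registration of two poses of the same specimen.

Generates two homonymous landmark sets related by a known rigid motion
(with a little placement noise), fits the rigid transform by the
cross-covariance SVD solution, and reports the recovery error and RMS
residual. The residual is the registration quality a user would see.
"""

import numpy as np

import voxscene as vx

true_t = vx.RigidTransform.from_axis_angle((1, 2, 0.5), 28.0)
true_t.translation[:] = (12.0, -4.0, 7.5)

for sigma in (0.0, 0.5):
    a, b = vx.fixtures.make_two_pose_landmarks(
        10, true_t, noise_sigma=sigma, rng_seed=17
    )
    fitted = vx.fit_rigid_landmarks(a, b)
    rms = vx.rms_residual(fitted, a.positions(), b.positions())
    rot_err = np.abs(fitted.rotation - true_t.rotation).max()
    print(
        f"noise sigma={sigma:3.1f} um  rotation error={rot_err:.2e}  "
        f"RMS residual={rms:.4f} um"
    )

print("\nWith zero noise the known motion is recovered to machine precision;")
print("with noise the RMS residual approaches sigma*sqrt(3) for many landmarks.")
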