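"""3D cropping: project a 2D polygon ROI through the view and clear voxels.

A rectangle covering the left half of an 8x8x4 volume (under the identity
view, 1 um = 1 projected unit) should clear exactly half of the voxels;
repeating the same crop changes nothing, because the voxels are already at
the fill value.
"""

import numpy as np

import voxscene as vx

vol = vx.ImageVolume(np.full((4, 8, 8), 200, np.uint8))
roi = vx.PolygonROI.rectangle(0, 0, 4, 8)

n1 = vx.crop_with_roi(vol, roi, np.eye(4), fill=0)
n2 = vx.crop_with_roi(vol, roi, np.eye(4), fill=0)
print(f"first crop modified {n1} voxels (expected 128 = half of 8*8*4)")
print(f"second identical crop modified {n2} voxels (idempotent)")

# the same ROI through a rotated view hits a different voxel set
rot = vx.RigidTransform.from_axis_angle((0, 0, 1), 45.0, center=(4, 4, 2)).matrix()
vol2 = vx.ImageVolume(np.full((4, 8, 8), 200, np.uint8))
n3 = vx.crop_with_roi(vol2, roi, rot, fill=0)
print(f"same ROI under a 45-degree view modified {n3} voxels")
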