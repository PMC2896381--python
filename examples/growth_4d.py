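"""4D playback of a voxel-editing growth simulation.

The dendritic-growth generator edits voxels frame by frame, producing a
time series in which the bright structure only ever grows. This script
plays the series with the VCR controls, pauses to annotate a time point,
and shows that edits stay confined to the paused frame.
"""

import numpy as np

import voxscene as vx

ts = vx.fixtures.dendritic_growth_sim(
    dims=(48, 48, 24), seed_point=(24, 24, 12), n_steps=12,
    branch_prob=0.2, rng_seed=5,
)

counts = [int((f.data > 0).sum()) for f in ts.frames]
print(f"{ts.n_frames} frames; bright-voxel counts: {counts}")

ts.play()
for _ in range(5):
    ts.tick()
ts.pause()
print(f"paused at t={ts.current_index}")

ts.annotate("growth-cone", (24.0, 24.0, 12.0), color=(0, 1, 0))
ts.edit_voxel(0, 0, 0, 255)
print("edited voxel (0,0,0) at the paused frame only:",
      [f.get_voxel(0, 0, 0) for f in ts.frames])

scene = vx.create_scene(128, 128)
scene.add_voltex(ts.current_frame)
scene.reset_view()
img = vx.snapshot(scene)
print("snapshot of the current time point:",
      int((img.pixels[:, :, :3].sum(axis=2) > 0).sum()), "lit pixels")
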