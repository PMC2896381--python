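"""Synthetic volumes and landmark sets for tests, examples, and demos.

Everything here is generated in memory — geometric phantoms (spheres,
bead fields), a stochastic dendritic-growth time series driven by direct
voxel editing, and paired landmark sets related by a known rigid motion.
All generators are pure functions of their arguments (including the RNG
seed): the same call always returns bitwise-identical data.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .landmarks import LandmarkSet
from .transforms import RigidTransform
from .volume import ImageVolume

__all__ = [
    "make_sphere_volume",
    "make_bead_volume",
    "dendritic_growth_sim",
    "make_two_pose_landmarks",
]


def _sphere_mask(dims, center, radius, calibration=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Boolean (nz, ny, nx) mask of voxels whose centers lie within radius
    of ``center`` (both in voxel units scaled by calibration)."""
    nx, ny, nz = dims
    cx, cy, cz = calibration
    x = (np.arange(nx) + 0.5) * cx - center[0] * cx
    y = (np.arange(ny) + 0.5) * cy - center[1] * cy
    z = (np.arange(nz) + 0.5) * cz - center[2] * cz
    d2 = (
        z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2
    )
    return d2 <= radius * radius


def make_sphere_volume(dims=(48, 48, 48), center=None, radius=20.0,
                       inside: int = 255, outside: int = 0,
                       calibration=(1.0, 1.0, 1.0),
                       bit_depth: int = 8) -> ImageVolume:
    """A solid-sphere phantom: voxels whose centers fall within ``radius``
    (voxel units) of ``center`` get ``inside``, the rest ``outside``.

    ``center`` defaults to the grid center (in voxel units, so the voxel
    (i, j, k) has center (i+0.5, j+0.5, k+0.5)).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    nx, ny, nz = dims
    if center is None:
        center = (nx / 2.0, ny / 2.0, nz / 2.0)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    data = np.full((nz, ny, nx), outside, dtype=dtype)
    data[_sphere_mask(dims, center, radius)] = inside
    return ImageVolume(data, calibration=calibration)


def make_bead_volume(dims=(64, 64, 64), bead_positions=None, bead_radius: float = 2.0,
                     intensity: int = 255, calibration=(1.0, 1.0, 1.0),
                     n_beads: Optional[int] = None, rng_seed: int = 0):
    """A fluorescent-bead phantom: the union of small bright spheres.

    ``bead_positions`` (voxel units) may be given explicitly; otherwise
    ``n_beads`` positions are drawn uniformly inside the grid (margin one
    bead radius) from a seeded RNG. Returns ``(volume, true_positions)``
    where the positions are the exact sphere centers, for use as ground
    truth in registration tests.
    """
    nx, ny, nz = dims
    if bead_positions is None:
        rng = np.random.default_rng(rng_seed)
        n = 10 if n_beads is None else int(n_beads)
        margin = bead_radius + 1
        bead_positions = np.column_stack(
            [rng.uniform(margin, d - margin, n) for d in (nx, ny, nz)]
        )
    positions = np.asarray(bead_positions, dtype=float)
    if positions.size == 0:
        positions = positions.reshape(0, 3)
    else:
        positions = np.atleast_2d(positions)
        if positions.shape[1] != 3:
            raise ValueError("bead positions must be (N, 3)")
    data = np.zeros((nz, ny, nx), dtype=np.uint8)
    for pos in positions:
        if not (0 <= pos[0] <= nx and 0 <= pos[1] <= ny and 0 <= pos[2] <= nz):
            raise ValueError(f"bead position {pos} outside grid {dims}")
        data[_sphere_mask(dims, pos, bead_radius)] = intensity
    vol = ImageVolume(data, calibration=calibration)
    return vol, positions.reshape(-1, 3)


# 26-connected neighborhood steps, excluding the null step
_NEIGHBOR_STEPS = np.array(
    [(dx, dy, dz)
     for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)]
)


def dendritic_growth_sim(dims=(64, 64, 32), seed_point=(32, 32, 16),
                         n_steps: int = 20, branch_prob: float = 0.1,
                         rng_seed: int = 0, intensity: int = 255,
                         calibration=(1.0, 1.0, 1.0)):
    """Simulate dendrite-like growth by direct voxel editing, one frame per
    growth step.

    Active tips take one 26-neighbor lattice step per frame, biased toward
    their previous direction (candidate steps within 90° of the previous
    one), branch with probability ``branch_prob``, and write maximal
    intensity into the volume. Frame t holds the cumulative structure
    after t steps; frame 0 is just the bright seed voxel. Deterministic
    for a given ``rng_seed``.

    Returns a :class:`~voxscene.animation.TimeSeriesContent`.
    """
    from .animation import TimeSeriesContent  # local import avoids a cycle

    nx, ny, nz = dims
    sx, sy, sz = (int(v) for v in seed_point)
    if not (0 <= sx < nx and 0 <= sy < ny and 0 <= sz < nz):
        raise ValueError(f"seed point {seed_point} outside grid {dims}")
    if not (0.0 <= branch_prob <= 1.0):
        raise ValueError("branch probability must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)

    data = np.zeros((nz, ny, nx), dtype=np.uint8)
    data[sz, sy, sx] = intensity
    frames = [ImageVolume(data.copy(), calibration=calibration)]

    tips = [(np.array([sx, sy, sz]), np.zeros(3))]  # (position, direction)
    for _ in range(n_steps):
        new_tips = []
        for pos, direction in tips:
            aligned = _NEIGHBOR_STEPS[_NEIGHBOR_STEPS @ direction >= 0]
            step = aligned[rng.integers(len(aligned))]
            nxt = pos + step
            if np.any(nxt < 0) or np.any(nxt >= np.array([nx, ny, nz])):
                nxt = pos  # tips stall at the border
            data[nxt[2], nxt[1], nxt[0]] = intensity
            new_tips.append((nxt, step.astype(float)))
            if rng.random() < branch_prob:
                branch_step = _NEIGHBOR_STEPS[rng.integers(len(_NEIGHBOR_STEPS))]
                bpos = pos + branch_step
                if np.all(bpos >= 0) and np.all(bpos < np.array([nx, ny, nz])):
                    data[bpos[2], bpos[1], bpos[0]] = intensity
                    new_tips.append((bpos, branch_step.astype(float)))
        tips = new_tips
        frames.append(ImageVolume(data.copy(), calibration=calibration))
    return TimeSeriesContent(frames)


def make_two_pose_landmarks(n: int, transform: RigidTransform,
                            noise_sigma: float = 0.0, rng_seed: int = 0,
                            extent: float = 100.0) -> tuple[LandmarkSet, LandmarkSet]:
    """Two homonymous landmark sets related by a known rigid motion.

    Set 1 holds ``n`` random points (uniform in a cube of side ``extent``
    µm); set 2 holds the same names at ``transform``-mapped positions plus
    isotropic Gaussian noise of standard deviation ``noise_sigma`` µm.
    Deterministic for a given ``rng_seed``.
    """
    if n < 3:
        raise ValueError("need at least 3 landmarks for a registration pair")
    rng = np.random.default_rng(rng_seed)
    pts = rng.uniform(0.0, extent, size=(n, 3))
    mapped = transform.apply(pts)
    if noise_sigma > 0:
        mapped = mapped + rng.normal(0.0, noise_sigma, size=mapped.shape)
    set1 = LandmarkSet(owner="pose-1")
    set2 = LandmarkSet(owner="pose-2")
    for k in range(n):
        name = f"lm-{k:03d}"
        set1.add(name, pts[k])
        set2.add(name, mapped[k])
    return set1, set2
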