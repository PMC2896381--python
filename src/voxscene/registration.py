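"""Landmark-based rigid registration and volume resampling.

Two sets of homonymous landmarks (same names, placed over corresponding
structures in two volumes) define point correspondences from which a rigid
transform — rotation plus translation, no scaling — is estimated in closed
form by the cross-covariance SVD (Kabsch) solution of the absolute
orientation problem, with the reflection case corrected so det(R) = +1.
The fitted transform can then resample one volume onto the grid of the
other for export.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DegenerateConfigurationError
from .landmarks import LandmarkSet
from .transforms import RigidTransform
from .volume import ImageVolume

__all__ = [
    "fit_rigid",
    "fit_rigid_landmarks",
    "rms_residual",
    "apply_rigid_resample",
]

log = logging.getLogger(__name__)


def _as_points(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"{name} must be an (N, 3) point array")
    return p


def fit_rigid(src, dst, with_scale: bool = False):
    """Least-squares rigid transform mapping ``src`` points onto ``dst``.

    Minimizes ``Σ‖R·srcᵢ + t − dstᵢ‖²`` over proper rotations R and
    translations t. Requires ≥ 3 non-collinear source points. With
    ``with_scale=True`` a similarity model is fitted instead and the
    isotropic scale is returned alongside the transform.

    Returns
    -------
    RigidTransform, or (RigidTransform, float) when ``with_scale``.
    """
    src = _as_points(src, "src")
    dst = _as_points(dst, "dst")
    if len(src) != len(dst):
        raise ValueError(f"point counts differ: {len(src)} vs {len(dst)}")
    if len(src) < 3:
        raise DegenerateConfigurationError(
            f"need at least 3 point pairs, got {len(src)}"
        )
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    src_c = src - cs
    dst_c = dst - cd
    if np.linalg.matrix_rank(src_c, tol=1e-9 * max(1.0, np.abs(src_c).max())) < 2:
        raise DegenerateConfigurationError("source landmarks are collinear")

    H = src_c.T @ dst_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    if with_scale:
        denom = (src_c ** 2).sum()
        scale = float((S @ np.diag(D).T).sum() / denom) if denom > 0 else 1.0
        t = cd - scale * R @ cs
        return RigidTransform(R, t), scale
    t = cd - R @ cs
    return RigidTransform(R, t)


def fit_rigid_landmarks(src: LandmarkSet, dst: LandmarkSet,
                        with_scale: bool = False):
    """Fit a rigid transform from homonymous landmarks (paired by name).

    Landmarks present in only one of the sets are ignored with a logged
    warning; at least 3 common names are required.
    """
    common = [n for n in src.names() if n in dst]
    unpaired = (set(src.names()) | set(dst.names())) - set(common)
    if unpaired:
        log.warning("ignoring unpaired landmarks: %s", sorted(unpaired))
    if not common:
        raise DegenerateConfigurationError("no common landmark names between sets")
    if len(common) < 3:
        raise DegenerateConfigurationError(
            f"need at least 3 homonymous landmarks, got {len(common)}"
        )
    s = np.array([src.get(n).position for n in common])
    d = np.array([dst.get(n).position for n in common])
    return fit_rigid(s, d, with_scale=with_scale)


def rms_residual(transform: RigidTransform, src, dst) -> float:
    """Root-mean-square registration residual ‖T(src) − dst‖ in µm."""
    src = _as_points(src, "src")
    dst = _as_points(dst, "dst")
    if len(src) != len(dst):
        raise ValueError(f"point counts differ: {len(src)} vs {len(dst)}")
    if len(src) == 0:
        raise ValueError("need at least one point pair")
    res = transform.apply(src) - dst
    return float(np.sqrt((res ** 2).sum(axis=1).mean()))


def apply_rigid_resample(vol: ImageVolume, transform: RigidTransform,
                         reference: Optional[ImageVolume] = None) -> ImageVolume:
    """Resample ``vol`` through a rigid transform onto a reference grid.

    Each output voxel center is pulled back through ``transform``⁻¹ and the
    source is sampled with trilinear interpolation; positions outside the
    source grid read 0. With no ``reference`` the output reuses the input
    geometry (dims, calibration, origin). The result is a regular stack,
    exportable with :func:`voxscene.volume.save_stack`.
    """
    ref = vol if reference is None else reference
    # output index -> reference physical -> (T⁻¹) source physical -> source index
    A = (
        np.linalg.inv(vol.index_to_physical_matrix())
        @ transform.inverse().matrix()
        @ ref.index_to_physical_matrix()
    )
    # scipy indexes (z, y, x); conjugate with the axis-reversal permutation
    P = np.zeros((4, 4))
    P[0, 2] = P[1, 1] = P[2, 0] = P[3, 3] = 1.0
    A_zyx = P @ A @ P
    out = ndimage.affine_transform(
        vol.data.astype(np.float32),
        A_zyx[:3, :3],
        offset=A_zyx[:3, 3],
        output_shape=tuple(reversed(ref.dims)),
        order=1,
        mode="grid-constant",
        cval=0.0,
    )
    out = np.clip(np.rint(out), 0, vol.max_intensity).astype(vol.data.dtype)
    return ImageVolume(out, calibration=ref.calibration, origin=ref.origin)
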