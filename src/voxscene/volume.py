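"""Calibrated image volumes: stack I/O, voxel editing, and ROI-projection cropping.

An :class:`ImageVolume` wraps a 3D grid of 8- or 16-bit intensities together
with its voxel calibration (physical extent per voxel, µm) and physical
origin. The voxel array is stored in ``(z, y, x)`` plane order, matching how
multi-page TIFF stacks are laid out on disk, while the public indexing API
uses ``(x, y, z)`` voxel coordinates.

Edits go through :meth:`ImageVolume.set_voxel` / :func:`crop_with_roi`, which
fire a change notification exactly once per mutating call so renderers and
cached isosurfaces can refresh themselves ("changes to voxel values are
propagated to the screen").
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import tifffile

from .errors import InvalidROIError, StackFormatError
from .transforms import RigidTransform

__all__ = ["ImageVolume", "PolygonROI", "load_stack", "save_stack", "crop_with_roi"]

log = logging.getLogger(__name__)

_ALLOWED_DTYPES = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


class ImageVolume:
    """A calibrated 3D voxel grid with change notification on edits.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx), dtype uint8 or uint16
        Voxel intensities in plane order (page, row, column).
    calibration : (cx, cy, cz), µm per voxel along each axis. All > 0.
    origin : (ox, oy, oz), physical offset of the grid corner, µm.

    The physical center of voxel ``(ix, iy, iz)`` is
    ``origin + (i + 0.5) * calibration`` per axis, so projection behavior is
    symmetric about the grid.
    """

    def __init__(self, data, calibration=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={data.ndim}")
        if data.dtype not in _ALLOWED_DTYPES:
            raise ValueError(
                f"unsupported dtype {data.dtype}; volumes are 8- or 16-bit unsigned"
            )
        if min(data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        calibration = tuple(float(c) for c in calibration)
        if len(calibration) != 3 or any(c <= 0 for c in calibration):
            raise ValueError("calibration must be three positive extents (µm)")
        self._data = data
        self.calibration = calibration
        self.origin = tuple(float(o) for o in origin)
        self._listeners: list[Callable[["ImageVolume"], None]] = []

    # -- basic geometry ----------------------------------------------
    @property
    def data(self) -> np.ndarray:
        """The (nz, ny, nx) voxel array. Mutate via set_voxel/crop_with_roi."""
        return self._data

    @property
    def dims(self) -> tuple[int, int, int]:
        """(nx, ny, nz) voxel counts."""
        nz, ny, nx = self._data.shape
        return nx, ny, nz

    @property
    def bit_depth(self) -> int:
        return _ALLOWED_DTYPES[self._data.dtype]

    @property
    def max_intensity(self) -> int:
        """Largest representable intensity, 2**bit_depth - 1."""
        return (1 << self.bit_depth) - 1

    def physical_extent(self) -> tuple[float, float, float]:
        nx, ny, nz = self.dims
        cx, cy, cz = self.calibration
        return nx * cx, ny * cy, nz * cz

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (min_corner, max_corner) of the grid, µm."""
        lo = np.asarray(self.origin, dtype=float)
        return lo, lo + np.asarray(self.physical_extent())

    def index_to_physical_matrix(self) -> np.ndarray:
        """4x4 mapping homogeneous voxel indices (ix,iy,iz,1) to voxel centers."""
        m = np.eye(4)
        m[:3, :3] = np.diag(self.calibration)
        m[:3, 3] = np.asarray(self.origin) + 0.5 * np.asarray(self.calibration)
        return m

    # -- change notification -----------------------------------------
    def subscribe(self, callback: Callable[["ImageVolume"], None]) -> Callable[[], None]:
        """Register an edit listener; returns an unsubscribe function."""
        self._listeners.append(callback)
        return lambda: self._listeners.remove(callback)

    def _notify(self) -> None:
        for cb in list(self._listeners):
            cb(self)

    # -- voxel access -------------------------------------------------
    def _check_index(self, x: int, y: int, z: int) -> None:
        nx, ny, nz = self.dims
        if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
            raise IndexError(f"voxel index ({x}, {y}, {z}) outside dims {self.dims}")

    def get_voxel(self, x: int, y: int, z: int) -> int:
        self._check_index(x, y, z)
        return int(self._data[z, y, x])

    def set_voxel(self, x: int, y: int, z: int, value: int) -> None:
        """Set one voxel; emits the change event once."""
        self._check_index(x, y, z)
        if not (0 <= value <= self.max_intensity):
            raise ValueError(
                f"value {value} outside [0, {self.max_intensity}] for "
                f"{self.bit_depth}-bit volume"
            )
        self._data[z, y, x] = value
        self._notify()

    def copy(self) -> "ImageVolume":
        return ImageVolume(self._data.copy(), self.calibration, self.origin)

    def __repr__(self):
        return (
            f"ImageVolume(dims={self.dims}, {self.bit_depth}-bit, "
            f"calibration={self.calibration})"
        )


class PolygonROI:
    """A closed 2D polygon in projected (viewport) coordinates.

    Membership uses the even-odd rule; points on the boundary count as
    inside. Only closed ROIs with >= 3 vertices are valid for cropping.
    """

    def __init__(self, vertices: Sequence[Sequence[float]], closed: bool = True):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) point list")
        self.vertices = v
        self.closed = bool(closed)

    @classmethod
    def rectangle(cls, x: float, y: float, w: float, h: float) -> "PolygonROI":
        return cls([(x, y), (x + w, y), (x + w, y + h), (x, y + h)])

    def validate_for_crop(self) -> None:
        if not self.closed:
            raise InvalidROIError("ROI must be closed for cropping")
        if len(self.vertices) < 3:
            raise InvalidROIError("closed ROI needs at least 3 vertices")

    def contains(self, points) -> np.ndarray:
        """Even-odd membership test for an (N, 2) array; boundary is inside."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        px, py = pts[:, 0], pts[:, 1]
        inside = np.zeros(len(pts), dtype=bool)
        boundary = np.zeros(len(pts), dtype=bool)
        verts = self.vertices
        scale = max(1.0, float(np.abs(verts).max()))
        eps = 1e-9 * scale
        n = len(verts)
        for i in range(n):
            x1, y1 = verts[i]
            x2, y2 = verts[(i + 1) % n]
            # on-segment test: colinear within eps and inside the segment bbox
            cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
            seg_len = np.hypot(x2 - x1, y2 - y1)
            if seg_len > 0:
                on = (np.abs(cross) <= eps * seg_len) & (
                    (px - x1) * (px - x2) + (py - y1) * (py - y2) <= eps * seg_len
                )
                boundary |= on
            # even-odd ray crossing (ray toward +x)
            crosses = (y1 > py) != (y2 > py)
            if np.any(crosses):
                with np.errstate(divide="ignore", invalid="ignore"):
                    xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                inside ^= crosses & (px < xint)
        return inside | boundary


def load_stack(path, calibration=None) -> ImageVolume:
    """Read a multi-page grayscale TIFF into an :class:`ImageVolume`.

    Voxel ``(x, y, z)`` is pixel ``(x, y)`` of page ``z``. Calibration is
    taken from the TIFF resolution tags and ImageJ-style ``spacing``
    metadata; an explicit ``calibration`` argument overrides both. If no
    calibration is stored, (1, 1, 1) µm is assumed with a logged warning.

    Raises
    ------
    StackFormatError
        Mixed page sizes/depths, or RGB / unsupported sample formats.
    """
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        first = pages[0]
        shape0, dtype0 = first.shape, first.dtype
        if first.samplesperpixel != 1 or len(shape0) != 2:
            raise StackFormatError(
                f"{path}: only single-channel grayscale stacks are supported"
            )
        if np.dtype(dtype0) not in _ALLOWED_DTYPES:
            raise StackFormatError(
                f"{path}: unsupported pixel type {dtype0}; expected uint8/uint16"
            )
        planes = []
        for k, page in enumerate(pages):
            if page.shape != shape0 or page.dtype != dtype0:
                raise StackFormatError(
                    f"{path}: page {k} has shape {page.shape}/{page.dtype}, "
                    f"expected {shape0}/{dtype0}"
                )
            planes.append(page.asarray())
        data = np.stack(planes, axis=0)

        if calibration is None:
            calibration = _read_calibration(tf, path)
    return ImageVolume(data, calibration=calibration)


def _read_calibration(tf: "tifffile.TiffFile", path) -> tuple[float, float, float]:
    page = tf.pages[0]
    tags = page.tags
    cx = cy = cz = None
    if "XResolution" in tags:
        num, den = tags["XResolution"].value
        if num:
            cx = den / num
    if "YResolution" in tags:
        num, den = tags["YResolution"].value
        if num:
            cy = den / num
    meta = tf.imagej_metadata or {}
    if "spacing" in meta:
        cz = float(meta["spacing"])
    if cx is None or cy is None or cz is None:
        log.warning("%s: no voxel calibration stored; assuming (1, 1, 1) µm", path)
        return (1.0, 1.0, 1.0)
    return (cx, cy, cz)


def save_stack(vol: ImageVolume, path) -> None:
    """Write a volume as a multi-page grayscale TIFF, z as page order.

    Calibration goes into the resolution tags (x/y) and ImageJ-style
    ``spacing`` metadata (z) so that :func:`load_stack` round-trips it.
    """
    cx, cy, cz = vol.calibration
    tifffile.imwrite(
        path,
        vol.data,
        imagej=True,
        resolution=(1.0 / cx, 1.0 / cy),
        metadata={"spacing": cz, "unit": "um", "axes": "ZYX"},
    )


def crop_with_roi(vol: ImageVolume, roi: PolygonROI, view, fill: int) -> int:
    """3D cropping: fill every voxel whose center projects inside a 2D ROI.

    The composite view transform ``view`` (a 4x4 homogeneous matrix or a
    :class:`~voxscene.transforms.RigidTransform`) maps physical voxel
    centers to the ROI plane; projection is orthographic (the z component
    is dropped). Voxels whose projected centers fall inside the polygon
    (even-odd rule, boundary inclusive) are set to ``fill``.

    Returns the number of voxels whose value actually changed; the change
    event fires once if that number is positive.
    """
    roi.validate_for_crop()
    if isinstance(view, RigidTransform):
        view = view.matrix()
    view = np.asarray(view, dtype=float)
    if view.shape != (4, 4):
        raise ValueError("view must be a 4x4 homogeneous matrix")
    if abs(np.linalg.det(view)) < 1e-12:
        raise ValueError("view transform must be invertible")
    if not (0 <= fill <= vol.max_intensity):
        raise ValueError(f"fill value {fill} outside intensity range")

    nx, ny, nz = vol.dims
    cx, cy, cz = vol.calibration
    ox, oy, oz = vol.origin
    xs = ox + (np.arange(nx) + 0.5) * cx
    ys = oy + (np.arange(ny) + 0.5) * cy
    modified = 0
    fill_cast = vol.data.dtype.type(fill)
    # one z-plane at a time keeps the exhaustive test memory-bounded
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    for iz in range(nz):
        pz = oz + (iz + 0.5) * cz
        pts = np.column_stack(
            [gx.ravel(), gy.ravel(), np.full(gx.size, pz), np.ones(gx.size)]
        )
        proj = pts @ view.T
        mask = roi.contains(proj[:, :2]).reshape(ny, nx)
        plane = vol.data[iz]
        changed = mask & (plane != fill_cast)
        n = int(changed.sum())
        if n:
            plane[changed] = fill_cast
            modified += n
    if modified:
        vol._notify()
    return modified
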