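"""Headless software rendering of scenes.

Three render paths share one orthographic camera model:

* **Volume rendering** — one ray per pixel through the composed
  (viewport ∘ view ∘ local) transform, trilinear sampling at a fixed step,
  front-to-back "over" compositing with early termination, using a transfer
  function in which dark voxels are more transparent than bright ones.
* **Orthoslices** — the three perpendicular planes x=ix, y=iy, z=iz drawn
  as textured quads with nearest-voxel lookup and z-buffer depth ordering.
* **Meshes** — flat-shaded, two-sided Lambert rasterization with a
  headlight (light along the view direction), z-buffered, back-to-front
  blended when transparent.

The camera looks along +z of viewer space from in front of the scene;
smaller viewer z is closer. Pixel (i, j) covers viewer coordinates
(i + 0.5, j + 0.5) after the scene's viewport centering, so with an
identity view a calibrated volume maps 1 µm to 1 px.

Snapshots draw meshes, orthoslices and landmark spheres into a shared
z-buffer first, then composite volume renderings over the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .meshing import PointMesh, TriangleMesh
from .scenegraph import Content, Scene
from .volume import ImageVolume

__all__ = [
    "RGBAImage",
    "TransferFunction",
    "classify",
    "composite_front_to_back",
    "default_sampling_step",
    "render_volume",
    "render_orthoslices",
    "render_mesh",
    "snapshot",
    "save_snapshot",
    "load_snapshot",
    "orthoslice_planes",
]

EARLY_TERMINATION_ALPHA = 0.999
_AMBIENT = 0.15  # keeps grazing faces distinguishable from the background


@dataclass
class RGBAImage:
    """A float RGBA raster with channels clamped to [0, 1]."""

    pixels: np.ndarray  # (H, W, 4)

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 3 or p.shape[2] != 4:
            raise ValueError("pixels must be (H, W, 4)")
        if not np.all(np.isfinite(p)):
            raise ValueError("pixel channels must be finite")
        self.pixels = np.clip(p, 0.0, 1.0)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def to_uint8(self) -> np.ndarray:
        return np.round(self.pixels * 255.0).astype(np.uint8)

    @classmethod
    def from_uint8(cls, arr) -> "RGBAImage":
        arr = np.asarray(arr)
        if arr.ndim == 3 and arr.shape[2] == 3:
            arr = np.concatenate([arr, np.full(arr.shape[:2] + (1,), 255, arr.dtype)], axis=2)
        return cls(arr.astype(float) / 255.0)


class TransferFunction:
    """Maps voxel intensity to color and opacity for compositing.

    The default opacity ramp is linear — ``alpha(i) = i / i_max`` scaled by
    ``1 - content_transparency`` — so dark voxels are more transparent than
    bright ones, alpha(0) = 0, and alpha is monotone non-decreasing. The
    default color map is the gray ramp modulated by the content color.
    Custom ``alpha_map`` / ``color_map`` callables (intensity → [0, 1] /
    RGB) may be supplied but must keep alpha monotone with alpha(0) = 0.
    """

    def __init__(self, max_intensity: int = 255, content_transparency: float = 0.0,
                 color=(1.0, 1.0, 1.0), alpha_map=None, color_map=None):
        if not (0.0 <= content_transparency <= 1.0):
            raise ValueError("content_transparency must be in [0, 1]")
        self.max_intensity = int(max_intensity)
        self.content_transparency = float(content_transparency)
        self.color = np.asarray(color, dtype=float)
        self.alpha_map = alpha_map
        self.color_map = color_map

    def alpha(self, intensity):
        i = np.asarray(intensity, dtype=float)
        if self.alpha_map is not None:
            a = np.asarray(self.alpha_map(i), dtype=float)
        else:
            a = i / self.max_intensity
        return np.clip(a, 0.0, 1.0) * (1.0 - self.content_transparency)

    def rgb(self, intensity):
        i = np.asarray(intensity, dtype=float)
        if self.color_map is not None:
            c = np.asarray(self.color_map(i), dtype=float)
        else:
            c = (np.clip(i / self.max_intensity, 0.0, 1.0))[..., None] * self.color
        return np.clip(c, 0.0, 1.0)

    def classify(self, intensity):
        """RGBA sample(s) for scalar or array intensity."""
        a = self.alpha(intensity)
        c = self.rgb(intensity)
        return np.concatenate([c, np.asarray(a)[..., None]], axis=-1)


def classify(tf: TransferFunction, intensity):
    """Functional form of :meth:`TransferFunction.classify`."""
    return tf.classify(intensity)


def composite_front_to_back(colors, alphas) -> tuple[np.ndarray, np.ndarray]:
    """Composite samples ordered front to back with the "over" operator.

    ``colors`` is (N, ..., 3) and ``alphas`` (N, ...); returns the final
    (..., 3) color and (...) alpha. Accumulation per sample is
    ``C += (1 - A) * a * c`` and ``A += (1 - A) * a``, stopping early once
    every pixel's alpha exceeds 0.999.
    """
    colors = np.asarray(colors, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    C = np.zeros(colors.shape[1:])
    A = np.zeros(alphas.shape[1:])
    for c, a in zip(colors, alphas):
        C = C + np.expand_dims((1.0 - A) * a, -1) * c
        A = A + (1.0 - A) * a
        if np.all(A >= EARLY_TERMINATION_ALPHA):
            break
    return C, A


def default_sampling_step(vol: ImageVolume) -> float:
    """Reference ray-sampling step: half the smallest voxel extent (µm)."""
    return 0.5 * min(vol.calibration)


# ---------------------------------------------------------------------------
# framebuffer

class _FrameBuffer:
    def __init__(self, scene: Scene):
        w, h = scene.viewport
        self.rgb = np.empty((h, w, 3))
        self.rgb[:] = np.asarray(scene.background, dtype=float)
        self.depth = np.full((h, w), np.inf)

    def image(self) -> RGBAImage:
        alpha = np.ones(self.rgb.shape[:2] + (1,))
        return RGBAImage(np.concatenate([np.clip(self.rgb, 0, 1), alpha], axis=2))


def _content_matrix(scene: Scene, content: Content) -> np.ndarray:
    """World(local content space, µm) → viewport pixel coordinates."""
    return scene.viewport_matrix() @ content.local_transform.matrix()


# ---------------------------------------------------------------------------
# volume ray casting

def _raycast_volume(scene: Scene, content: Content, C, A, step: Optional[float]):
    vol: ImageVolume = content.source
    M = _content_matrix(scene, content) @ vol.index_to_physical_matrix()
    Minv = np.linalg.inv(M)

    nx, ny, nz = vol.dims
    corners = np.array(
        [[x, y, z, 1.0]
         for x in (-0.5, nx - 0.5)
         for y in (-0.5, ny - 0.5)
         for z in (-0.5, nz - 0.5)]
    )
    view_corners = corners @ M.T
    zmin, zmax = view_corners[:, 2].min(), view_corners[:, 2].max()
    if zmax <= zmin:
        zmax = zmin + 1e-9

    ref_step = default_sampling_step(vol)
    step_world = ref_step if step is None else float(step)
    if step_world <= 0:
        raise ValueError("sampling step must be positive")
    step_view = step_world * scene.view_zoom
    n_steps = max(1, int(np.ceil((zmax - zmin) / step_view)))
    correction = step_world / ref_step  # opacity correction exponent

    w, h = scene.viewport
    px = np.arange(w) + 0.5
    py = np.arange(h) + 0.5
    gx, gy = np.meshgrid(px, py)  # (h, w)
    # affine decomposition: idx = base + z * dz
    base = (Minv[:3, 0][:, None, None] * gx + Minv[:3, 1][:, None, None] * gy
            + Minv[:3, 3][:, None, None])
    dz = Minv[:3, 2]

    tf = TransferFunction(
        max_intensity=vol.max_intensity,
        content_transparency=content.transparency,
        color=content.color,
    )
    data = vol.data.astype(np.float32)
    zs = zmin + (np.arange(n_steps) + 0.5) * step_view
    zs = zs[zs <= zmax]
    for z in zs:
        idx = base + dz[:, None, None] * z  # (3, h, w) in (ix, iy, iz)
        intensity = ndimage.map_coordinates(
            data, [idx[2], idx[1], idx[0]], order=1, mode="grid-constant", cval=0.0
        )
        a = tf.alpha(intensity)
        if correction != 1.0:
            a = 1.0 - (1.0 - a) ** correction
        c = tf.rgb(intensity)
        np.add(C, ((1.0 - A) * a)[..., None] * c, out=C)
        np.add(A, (1.0 - A) * a, out=A)
        if np.all(A >= EARLY_TERMINATION_ALPHA):
            break


def render_volume(scene: Scene, step: Optional[float] = None) -> RGBAImage:
    """Ray-cast all visible volume-rendering contents over the background.

    ``step`` overrides the world-space sampling step (µm); opacity
    correction ``a' = 1 - (1 - a)**(step/ref)`` keeps the composite
    consistent across sampling rates.
    """
    w, h = scene.viewport
    C = np.zeros((h, w, 3))
    A = np.zeros((h, w))
    for content in scene.visible_contents(kinds=("voltex",)):
        _raycast_volume(scene, content, C, A, step)
    bg = np.asarray(scene.background, dtype=float)
    out = C + (1.0 - A)[..., None] * bg
    alpha = np.ones((h, w, 1))
    return RGBAImage(np.concatenate([np.clip(out, 0, 1), alpha], axis=2))


def _composite_volumes_over(scene: Scene, fb: _FrameBuffer, step=None):
    h, w = fb.rgb.shape[:2]
    C = np.zeros((h, w, 3))
    A = np.zeros((h, w))
    any_volume = False
    for content in scene.visible_contents(kinds=("voltex",)):
        any_volume = True
        _raycast_volume(scene, content, C, A, step)
    if any_volume:
        fb.rgb = C + (1.0 - A)[..., None] * fb.rgb


# ---------------------------------------------------------------------------
# orthoslices

def orthoslice_planes(content: Content):
    """The three textured planes of an orthoslice content.

    Each plane is (p00, e1, e2, axis) in continuous voxel-index space: the
    quad spans p00 + s*e1 + t*e2 with s, t in [0, 1]; ``axis`` is the fixed
    axis (0=x, 1=y, 2=z).
    """
    if content.kind != "orthoslices":
        raise ValueError("content is not an orthoslice set")
    nx, ny, nz = content.source.dims
    ix, iy, iz = content.slice_positions
    return [
        (np.array([ix, -0.5, -0.5]), np.array([0.0, ny, 0.0]), np.array([0.0, 0.0, nz]), 0),
        (np.array([-0.5, iy, -0.5]), np.array([nx, 0.0, 0.0]), np.array([0.0, 0.0, nz]), 1),
        (np.array([-0.5, -0.5, iz]), np.array([nx, 0.0, 0.0]), np.array([0.0, ny, 0.0]), 2),
    ]


def _raster_orthoslices(scene: Scene, content: Content, fb: _FrameBuffer):
    vol: ImageVolume = content.source
    M = _content_matrix(scene, content) @ vol.index_to_physical_matrix()
    nx, ny, nz = vol.dims
    dims = np.array([nx, ny, nz])
    tf = TransferFunction(
        max_intensity=vol.max_intensity,
        content_transparency=content.transparency,
        color=content.color,
    )
    h, w = fb.rgb.shape[:2]
    opacity = 1.0 - content.transparency
    for p00, e1, e2, _axis in orthoslice_planes(content):
        q0 = M @ np.append(p00, 1.0)
        v1 = M[:3, :3] @ e1
        v2 = M[:3, :3] @ e2
        J = np.array([[v1[0], v2[0]], [v1[1], v2[1]]])
        det = np.linalg.det(J)
        if abs(det) < 1e-9:
            continue  # edge-on plane projects to a line
        Jinv = np.linalg.inv(J)
        xs = np.array([q0[0], q0[0] + v1[0], q0[0] + v2[0], q0[0] + v1[0] + v2[0]])
        ys = np.array([q0[1], q0[1] + v1[1], q0[1] + v2[1], q0[1] + v1[1] + v2[1]])
        x0 = max(0, int(np.floor(xs.min() - 0.5)))
        x1 = min(w, int(np.ceil(xs.max() + 0.5)))
        y0 = max(0, int(np.floor(ys.min() - 0.5)))
        y1 = min(h, int(np.ceil(ys.max() + 0.5)))
        if x0 >= x1 or y0 >= y1:
            continue
        gx, gy = np.meshgrid(np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5)
        rel = np.stack([gx - q0[0], gy - q0[1]])
        st = np.einsum("ij,j...->i...", Jinv, rel)
        s, t = st[0], st[1]
        mask = (s >= 0) & (s <= 1) & (t >= 0) & (t <= 1)
        if not mask.any():
            continue
        z = q0[2] + s * v1[2] + t * v2[2]
        region = (slice(y0, y1), slice(x0, x1))
        visible = mask & (z < fb.depth[region])
        if not visible.any():
            continue
        idx = (p00[:, None] + np.outer(e1, s[visible]) + np.outer(e2, t[visible]))
        vox = np.clip(np.rint(idx).astype(int), 0, (dims - 1)[:, None])
        intensity = vol.data[vox[2], vox[1], vox[0]]
        color = tf.rgb(intensity)
        sub_rgb = fb.rgb[region]
        sub_rgb[visible] = opacity * color + (1 - opacity) * sub_rgb[visible]
        if opacity >= EARLY_TERMINATION_ALPHA:
            sub_depth = fb.depth[region]
            sub_depth[visible] = z[visible]


def render_orthoslices(scene: Scene) -> RGBAImage:
    """Render only the visible orthoslice contents (three planes each)."""
    fb = _FrameBuffer(scene)
    for content in scene.visible_contents(kinds=("orthoslices",)):
        _raster_orthoslices(scene, content, fb)
    return fb.image()


# ---------------------------------------------------------------------------
# mesh rasterization

def _raster_triangle_mesh(fb: _FrameBuffer, verts_px: np.ndarray, tris: np.ndarray,
                          color, transparency: float):
    if not len(tris):
        return
    h, w = fb.rgb.shape[:2]
    color = np.asarray(color, dtype=float)
    opacity = 1.0 - transparency
    a = verts_px[tris[:, 0]]
    b = verts_px[tris[:, 1]]
    c = verts_px[tris[:, 2]]
    normals = np.cross(b - a, c - a)
    norms = np.linalg.norm(normals, axis=1)
    # two-sided headlight Lambert: |n·view| with a small ambient floor
    with np.errstate(invalid="ignore", divide="ignore"):
        cosines = np.abs(normals[:, 2]) / np.where(norms > 0, norms, 1.0)
    shades = _AMBIENT + (1.0 - _AMBIENT) * cosines
    # painter's order: far (large z) first so transparency blends correctly
    order = np.argsort(-(a[:, 2] + b[:, 2] + c[:, 2]))
    for fi in order:
        v0, v1, v2 = a[fi], b[fi], c[fi]
        area = (v1[0] - v0[0]) * (v2[1] - v0[1]) - (v1[1] - v0[1]) * (v2[0] - v0[0])
        if area == 0.0:
            continue
        x0 = max(0, int(np.floor(min(v0[0], v1[0], v2[0]) - 0.5)))
        x1 = min(w, int(np.ceil(max(v0[0], v1[0], v2[0]) + 0.5)))
        y0 = max(0, int(np.floor(min(v0[1], v1[1], v2[1]) - 0.5)))
        y1 = min(h, int(np.ceil(max(v0[1], v1[1], v2[1]) + 0.5)))
        if x0 >= x1 or y0 >= y1:
            continue
        gx, gy = np.meshgrid(np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5)
        w0 = ((v1[0] - v0[0]) * (gy - v0[1]) - (v1[1] - v0[1]) * (gx - v0[0])) / area
        w1 = ((v2[0] - v1[0]) * (gy - v1[1]) - (v2[1] - v1[1]) * (gx - v1[0])) / area
        w2 = 1.0 - w0 - w1
        mask = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not mask.any():
            continue
        z = w1 * v0[2] + w2 * v1[2] + w0 * v2[2]
        region = (slice(y0, y1), slice(x0, x1))
        visible = mask & (z < fb.depth[region])
        if not visible.any():
            continue
        shaded = np.clip(shades[fi], 0, 1) * color
        sub = fb.rgb[region]
        sub[visible] = opacity * shaded + (1 - opacity) * sub[visible]
        if opacity >= EARLY_TERMINATION_ALPHA:
            depth = fb.depth[region]
            depth[visible] = z[visible]


def _raster_disks(fb: _FrameBuffer, centers_px: np.ndarray, radii_px, colors):
    """Screen-space filled disks (point-mesh points and landmark spheres)."""
    h, w = fb.rgb.shape[:2]
    radii_px = np.broadcast_to(np.asarray(radii_px, dtype=float), (len(centers_px),))
    colors = np.broadcast_to(np.asarray(colors, dtype=float), (len(centers_px), 3))
    for (cx, cy, cz), r, col in zip(centers_px, radii_px, colors):
        r = max(r, 0.5)
        x0 = max(0, int(np.floor(cx - r)))
        x1 = min(w, int(np.ceil(cx + r)) + 1)
        y0 = max(0, int(np.floor(cy - r)))
        y1 = min(h, int(np.ceil(cy + r)) + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        gx, gy = np.meshgrid(np.arange(x0, x1) + 0.5, np.arange(y0, y1) + 0.5)
        mask = (gx - cx) ** 2 + (gy - cy) ** 2 <= r * r
        region = (slice(y0, y1), slice(x0, x1))
        visible = mask & (cz < fb.depth[region])
        if not visible.any():
            continue
        fb.rgb[region][visible] = col
        fb.depth[region][visible] = cz


def _project(M: np.ndarray, points: np.ndarray) -> np.ndarray:
    hom = np.column_stack([points, np.ones(len(points))])
    return (hom @ M.T)[:, :3]


def _raster_mesh_content(scene: Scene, content: Content, fb: _FrameBuffer):
    M = _content_matrix(scene, content)
    mesh = content.mesh
    if mesh is not None:
        if mesh.n_triangles:
            verts_px = _project(M, mesh.vertices)
            _raster_triangle_mesh(fb, verts_px, mesh.triangles, content.color,
                                  content.transparency)
    elif isinstance(content.source, PointMesh):
        pm = content.source
        if pm.n_points:
            centers = _project(M, pm.points)
            color = np.asarray(content.color) * np.asarray(pm.color)
            _raster_disks(fb, centers, pm.point_size / 2.0, color)


def _raster_landmarks(scene: Scene, content: Content, fb: _FrameBuffer):
    marks = list(content.landmarks)
    if not marks:
        return
    M = _content_matrix(scene, content)
    centers = _project(M, np.array([m.position for m in marks]))
    radii = np.array([m.radius for m in marks]) * scene.view_zoom
    colors = np.array([m.color for m in marks])
    _raster_disks(fb, centers, radii, colors)


def render_mesh(scene: Scene) -> RGBAImage:
    """Render only the visible mesh contents (isosurfaces, custom meshes)."""
    fb = _FrameBuffer(scene)
    for content in scene.visible_contents(kinds=("isosurface", "custom-mesh")):
        _raster_mesh_content(scene, content, fb)
    return fb.image()


# ---------------------------------------------------------------------------
# snapshots

def snapshot(scene: Scene) -> RGBAImage:
    """Render every visible content of every kind into one image.

    Meshes, orthoslices and landmark spheres share a z-buffer; volume
    renderings are composited over the result last.
    """
    fb = _FrameBuffer(scene)
    for content in scene.visible_contents(kinds=("isosurface", "custom-mesh")):
        _raster_mesh_content(scene, content, fb)
    for content in scene.visible_contents(kinds=("orthoslices",)):
        _raster_orthoslices(scene, content, fb)
    for content in scene.visible_contents():
        _raster_landmarks(scene, content, fb)
    _composite_volumes_over(scene, fb)
    return fb.image()


def save_snapshot(scene: Scene, path) -> None:
    """Snapshot the scene and write it as an 8-bit RGBA PNG."""
    iio.imwrite(path, snapshot(scene).to_uint8(), extension=".png")


def load_snapshot(path) -> RGBAImage:
    """Read a PNG back into an :class:`RGBAImage` (8-bit quantized)."""
    return RGBAImage.from_uint8(iio.imread(path))
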