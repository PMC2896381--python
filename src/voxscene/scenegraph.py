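"""The 3D scene: viewport, view-transform chain, and named contents.

A :class:`Scene` plays the role the scene-graph "universe" plays in
interactive viewers: it owns the viewport, the background color, a global
view-transform chain (zoom ∘ rotation ∘ pan, applied in that fixed order),
and a registry of uniquely named :class:`Content` instances. Each content
wraps one displayable element — a volume rendering ("voltex"), an
isosurface, an orthoslice set, or a custom mesh — together with its color,
transparency, local rigid transform, visibility switch, and landmarks.

Everything is headless: the scene holds state and transforms; rendering
lives in :mod:`voxscene.rendering`.
"""

from __future__ import annotations

from typing import Callable, Optional, Union

import numpy as np

from .errors import NameCollisionError, NotFoundError
from .landmarks import LandmarkSet
from .meshing import PointMesh, TriangleMesh, marching_cubes
from .transforms import RigidTransform, rotation_about_axis
from .volume import ImageVolume

__all__ = ["Scene", "Content", "create_scene", "KINDS"]

KINDS = ("voltex", "isosurface", "orthoslices", "custom-mesh")

_VOLUME_KINDS = ("voltex", "isosurface", "orthoslices")


class Content:
    """One named displayable element of a scene.

    Exactly one ``kind`` per content; kind-specific state (isosurface
    threshold, orthoslice positions) exists only for that kind. A content
    starts visible, fully opaque, and white, with an identity local
    transform.
    """

    def __init__(self, name: str, kind: str, source, *, threshold=None, scene=None):
        if kind not in KINDS:
            raise ValueError(f"unknown content kind '{kind}'")
        if kind in _VOLUME_KINDS and not isinstance(source, ImageVolume):
            raise TypeError(f"kind '{kind}' requires an ImageVolume source")
        if kind == "custom-mesh" and not isinstance(source, (TriangleMesh, PointMesh)):
            raise TypeError("kind 'custom-mesh' requires a TriangleMesh or PointMesh")
        self.name = name
        self.kind = kind
        self.source = source
        self.color = (1.0, 1.0, 1.0)
        self._transparency = 0.0
        self._local_transform = RigidTransform.identity()
        self.visible = True
        self.landmarks = LandmarkSet(owner=name)
        self._scene = scene
        self._mesh_cache: Optional[TriangleMesh] = None

        if kind == "isosurface":
            if threshold is None:
                threshold = source.max_intensity // 2
            self.threshold = float(threshold)
            source.subscribe(self._on_volume_change)
        elif kind == "orthoslices":
            nx, ny, nz = source.dims
            self.slice_positions = (nx // 2, ny // 2, nz // 2)
        if kind == "voltex":
            source.subscribe(self._on_volume_change)

    # -- properties ----------------------------------------------------
    @property
    def transparency(self) -> float:
        return self._transparency

    @transparency.setter
    def transparency(self, value: float):
        value = float(value)
        if not (0.0 <= value <= 1.0):
            raise ValueError("transparency must be in [0, 1]")
        self._transparency = value

    @property
    def local_transform(self) -> RigidTransform:
        return self._local_transform

    def set_local_transform(self, transform: RigidTransform) -> None:
        """Replace the local transform; counts as a transform event."""
        if not isinstance(transform, RigidTransform):
            raise TypeError("local transform must be a RigidTransform")
        self._local_transform = transform
        if self._scene is not None:
            self._scene._notify_transform()

    def set_slice_positions(self, ix: int, iy: int, iz: int) -> None:
        """Move the three orthoslice planes (orthoslices contents only)."""
        if self.kind != "orthoslices":
            raise ValueError("slice positions only apply to orthoslice contents")
        nx, ny, nz = self.source.dims
        if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
            raise IndexError(f"slice positions ({ix}, {iy}, {iz}) outside dims {self.source.dims}")
        self.slice_positions = (ix, iy, iz)

    def _on_volume_change(self, _vol) -> None:
        self._mesh_cache = None

    @property
    def mesh(self) -> Optional[TriangleMesh]:
        """The renderable mesh: the source for custom meshes, a (cached)
        marching-cubes extraction for isosurfaces, else None."""
        if self.kind == "custom-mesh" and isinstance(self.source, TriangleMesh):
            return self.source
        if self.kind == "isosurface":
            if self._mesh_cache is None:
                self._mesh_cache = marching_cubes(self.source, self.threshold)
            return self._mesh_cache
        return None

    def bounding_box(self):
        """World-space axis-aligned bounds of this content (after the local
        transform), or None for empty geometry."""
        if isinstance(self.source, ImageVolume):
            lo, hi = self.source.bounding_box()
        else:
            if (isinstance(self.source, TriangleMesh) and not self.source.n_vertices) or (
                isinstance(self.source, PointMesh) and not self.source.n_points
            ):
                return None
            lo, hi = self.source.bounding_box()
        corners = np.array(
            [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
        )
        world = self._local_transform.apply(corners)
        return world.min(axis=0), world.max(axis=0)

    def __repr__(self):
        return f"Content('{self.name}', kind={self.kind}, visible={self.visible})"


class Scene:
    """Viewport + background + view chain + named-content registry.

    The composite view transform maps world (µm) coordinates to viewer
    coordinates: ``view = Zoom ∘ Rotation ∘ Pan`` (pan applied first). The
    viewport mapping additionally re-centers viewer coordinates on the
    viewport center, so that viewer-space origin lands mid-image.
    """

    def __init__(self, width: int, height: int):
        width, height = int(width), int(height)
        if width < 1 or height < 1:
            raise ValueError("viewport dimensions must be >= 1")
        self.viewport = (width, height)
        self.background = (0.0, 0.0, 0.0)
        self.view_zoom = 1.0
        self.view_rotation = np.eye(3)
        self.view_pan = np.zeros(3)
        self.contents: dict[str, Content] = {}
        self.selected: Optional[str] = None
        self._auto_counters: dict[str, int] = {}
        self._transform_listeners: list[Callable[[], None]] = []

    # -- view chain ----------------------------------------------------
    def composite_view(self) -> np.ndarray:
        """4x4 matrix Zoom @ Rotation @ Pan (world µm → viewer coords)."""
        pan = np.eye(4)
        pan[:3, 3] = self.view_pan
        rot = np.eye(4)
        rot[:3, :3] = self.view_rotation
        zoom = np.diag([self.view_zoom] * 3 + [1.0])
        return zoom @ rot @ pan

    def viewport_matrix(self) -> np.ndarray:
        """World → viewport pixel coordinates (viewer origin at center)."""
        w, h = self.viewport
        center = np.eye(4)
        center[0, 3] = w / 2.0
        center[1, 3] = h / 2.0
        return center @ self.composite_view()

    def zoom(self, factor: float) -> None:
        if factor <= 0:
            raise ValueError("zoom factor must be positive")
        self.view_zoom *= float(factor)
        self._notify_transform()

    def rotate(self, axis, angle_deg: float) -> None:
        """Compose an incremental rotation about ``axis`` (degrees)."""
        inc = rotation_about_axis(axis, angle_deg)
        self.view_rotation = inc @ self.view_rotation
        self._notify_transform()

    def pan(self, delta) -> None:
        self.view_pan = self.view_pan + np.asarray(delta, dtype=float)
        self._notify_transform()

    def reset_view(self) -> None:
        """Identity chain, then fit: pan brings the union bounding box of the
        visible contents to the viewer origin and zoom scales its larger
        projected extent to 90% of the shorter viewport side."""
        self.view_rotation = np.eye(3)
        self.view_zoom = 1.0
        self.view_pan = np.zeros(3)
        boxes = [c.bounding_box() for c in self.contents.values() if c.visible]
        boxes = [b for b in boxes if b is not None]
        if boxes:
            lo = np.min([b[0] for b in boxes], axis=0)
            hi = np.max([b[1] for b in boxes], axis=0)
            extent = float(max(hi[0] - lo[0], hi[1] - lo[1]))
            self.view_pan = -(lo + hi) / 2.0
            if extent > 0:
                self.view_zoom = 0.9 * min(self.viewport) / extent
        self._notify_transform()

    # -- transform events ------------------------------------------------
    def subscribe_transforms(self, callback: Callable[[], None]) -> Callable[[], None]:
        """Observe transform-mutating operations; returns unsubscribe."""
        self._transform_listeners.append(callback)
        return lambda: self._transform_listeners.remove(callback)

    def _notify_transform(self) -> None:
        for cb in list(self._transform_listeners):
            cb()

    # -- content registry ------------------------------------------------
    def _auto_name(self, kind: str) -> str:
        stem = {"voltex": "Voltex", "isosurface": "Isosurface",
                "orthoslices": "Orthoslices", "custom-mesh": "Mesh"}[kind]
        while True:
            self._auto_counters[kind] = self._auto_counters.get(kind, 0) + 1
            name = f"{stem}-{self._auto_counters[kind]}"
            if name not in self.contents:
                return name

    def add_content(self, source, kind: str, name: Optional[str] = None,
                    threshold=None) -> Content:
        """Register a new content; auto-named '<Kind>-<n>' if unnamed.

        Orthoslice contents start at the volume mid-planes; isosurfaces
        default their threshold to half the intensity range.
        """
        if name is None:
            name = self._auto_name(kind)
        elif name in self.contents:
            raise NameCollisionError(f"content name '{name}' already in scene")
        content = Content(name, kind, source, threshold=threshold, scene=self)
        self.contents[name] = content
        return content

    def add_voltex(self, vol: ImageVolume, name: Optional[str] = None) -> Content:
        return self.add_content(vol, "voltex", name)

    def add_orthoslice(self, vol: ImageVolume, name: Optional[str] = None) -> Content:
        return self.add_content(vol, "orthoslices", name)

    def add_isosurface(self, vol: ImageVolume, threshold=None,
                       name: Optional[str] = None) -> Content:
        return self.add_content(vol, "isosurface", name, threshold=threshold)

    def add_custom_mesh(self, mesh: Union[TriangleMesh, PointMesh],
                        name: Optional[str] = None) -> Content:
        return self.add_content(mesh, "custom-mesh", name)

    def get_content(self, name: str) -> Content:
        try:
            return self.contents[name]
        except KeyError:
            raise NotFoundError(f"no content named '{name}'") from None

    def remove_content(self, name: str) -> None:
        if name not in self.contents:
            raise NotFoundError(f"no content named '{name}'")
        del self.contents[name]
        if self.selected == name:
            self.selected = None

    def select(self, name: Optional[str]) -> None:
        if name is not None and name not in self.contents:
            raise NotFoundError(f"no content named '{name}'")
        self.selected = name

    def visible_contents(self, kinds=None):
        for c in self.contents.values():
            if c.visible and (kinds is None or c.kind in kinds):
                yield c

    def __len__(self):
        return len(self.contents)

    def __repr__(self):
        return f"Scene({self.viewport[0]}x{self.viewport[1]}, {len(self)} contents)"


def create_scene(width: int, height: int) -> Scene:
    """New empty scene with an identity view and a black background."""
    return Scene(width, height)
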