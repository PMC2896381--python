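"""4D playback, rotation recording, and transform-event recording.

A :class:`TimeSeriesContent` holds an ordered list of equally shaped,
equally calibrated volumes (one per time point) with VCR-style controls:
play/pause, single stepping, jump to first/last. While paused, the current
frame can be edited and annotated like any static volume; edits never leak
into neighboring frames.

Animation products are :class:`FrameStack`s — ordered lists of rendered
RGBA frames — either from a 360° rotation of the scene or from recording
every transform-mutating operation between ``start_recording`` and
``stop_recording``. Frame stacks save to multi-page RGB TIFF; video
encoding is out of scope.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import tifffile

from .errors import StateError
from .landmarks import LandmarkSet
from .rendering import RGBAImage, snapshot
from .scenegraph import Scene
from .volume import ImageVolume

__all__ = [
    "TimeSeriesContent",
    "FrameStack",
    "record_rotation",
    "start_recording",
    "stop_recording",
    "save_frames",
    "load_frames",
]

DEFAULT_ROTATION_AXIS = (0.0, 1.0, 0.0)  # scene-vertical
DEFAULT_ROTATION_STEP_DEG = 2.0


class TimeSeriesContent:
    """An ordered 4D series of volumes sharing dims and calibration."""

    def __init__(self, frames: list[ImageVolume], loop: bool = False):
        if not frames:
            raise ValueError("a time series needs at least one frame")
        dims0, cal0 = frames[0].dims, frames[0].calibration
        for k, f in enumerate(frames):
            if f.dims != dims0:
                raise ValueError(f"frame {k} dims {f.dims} differ from {dims0}")
            if f.calibration != cal0:
                raise ValueError(f"frame {k} calibration differs from {cal0}")
        self.frames = list(frames)
        self.frame_landmarks = [LandmarkSet(owner=f"t{k}") for k in range(len(frames))]
        self.current_index = 0
        self.playing = False
        self.loop = bool(loop)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def current_frame(self) -> ImageVolume:
        return self.frames[self.current_index]

    @property
    def current_landmarks(self) -> LandmarkSet:
        return self.frame_landmarks[self.current_index]

    # -- playback controls -------------------------------------------
    def play(self) -> None:
        self.playing = True

    def pause(self) -> None:
        self.playing = False

    def tick(self) -> None:
        """Advance one frame if playing; clamps at the last frame (or wraps
        when looping)."""
        if not self.playing:
            return
        nxt = self.current_index + 1
        if nxt >= self.n_frames:
            self.current_index = 0 if self.loop else self.n_frames - 1
        else:
            self.current_index = nxt

    def step_forward(self) -> None:
        self.current_index = min(self.current_index + 1, self.n_frames - 1)

    def step_back(self) -> None:
        self.current_index = max(self.current_index - 1, 0)

    def first(self) -> None:
        self.current_index = 0

    def last(self) -> None:
        self.current_index = self.n_frames - 1

    # -- paused-frame editing ----------------------------------------
    def _require_paused(self) -> None:
        if self.playing:
            raise StateError("pause playback before editing the current frame")

    def edit_voxel(self, x: int, y: int, z: int, value: int) -> None:
        """Edit one voxel of the current frame (paused only)."""
        self._require_paused()
        self.current_frame.set_voxel(x, y, z, value)

    def annotate(self, name: str, position, **kwargs) -> None:
        """Add a landmark to the current time point (paused only)."""
        self._require_paused()
        self.current_landmarks.add(name, position, **kwargs)

    def __len__(self):
        return self.n_frames


class FrameStack:
    """An ordered stack of equally sized rendered frames."""

    def __init__(self, frames: Optional[list[RGBAImage]] = None):
        self.frames: list[RGBAImage] = []
        for f in frames or []:
            self.append(f)

    def append(self, frame: RGBAImage) -> None:
        if self.frames and (frame.width, frame.height) != (
            self.frames[0].width,
            self.frames[0].height,
        ):
            raise ValueError("all frames in a stack must share dimensions")
        self.frames.append(frame)

    def __len__(self):
        return len(self.frames)

    def __getitem__(self, k) -> RGBAImage:
        return self.frames[k]


def record_rotation(scene: Scene, axis=DEFAULT_ROTATION_AXIS,
                    step_deg: float = DEFAULT_ROTATION_STEP_DEG) -> FrameStack:
    """Record a full 360° rotation of the scene as rendered frames.

    Frame k (k = 1 … 360/step) is the snapshot after a cumulative rotation
    of k·step degrees about ``axis``; the accumulated rotation sums to
    360°. The view state is restored exactly afterwards, so the scene is
    bitwise-unchanged by the recording.
    """
    step_deg = float(step_deg)
    if not (0 < step_deg <= 360) or (360.0 % step_deg) != 0:
        raise ValueError(f"step {step_deg}° must positively divide 360°")
    n = int(round(360.0 / step_deg))
    saved_rotation = scene.view_rotation.copy()
    saved_zoom = scene.view_zoom
    saved_pan = scene.view_pan.copy()
    stack = FrameStack()
    try:
        for _ in range(n):
            scene.rotate(axis, step_deg)
            stack.append(snapshot(scene))
    finally:
        scene.view_rotation = saved_rotation
        scene.view_zoom = saved_zoom
        scene.view_pan = saved_pan
    return stack


def start_recording(scene: Scene) -> None:
    """Record one rendered frame per transform-mutating operation
    (zoom/rotate/pan/local-transform change) until :func:`stop_recording`."""
    if getattr(scene, "_recording", None) is not None:
        raise StateError("recording already in progress")
    stack = FrameStack()

    def on_transform():
        stack.append(snapshot(scene))

    unsubscribe = scene.subscribe_transforms(on_transform)
    scene._recording = (stack, unsubscribe)


def stop_recording(scene: Scene) -> FrameStack:
    """Stop transform-event recording and return the captured frames."""
    rec = getattr(scene, "_recording", None)
    if rec is None:
        raise StateError("no recording in progress")
    stack, unsubscribe = rec
    unsubscribe()
    scene._recording = None
    return stack


def save_frames(stack: FrameStack, path) -> None:
    """Write a nonempty frame stack as a multi-page RGB TIFF."""
    if not len(stack):
        raise ValueError("cannot save an empty frame stack")
    pages = np.stack([f.to_uint8()[:, :, :3] for f in stack.frames])
    tifffile.imwrite(path, pages, photometric="rgb")


def load_frames(path) -> FrameStack:
    """Read a frame stack written by :func:`save_frames`."""
    pages = tifffile.imread(path)
    if pages.ndim == 3:  # single page
        pages = pages[None]
    return FrameStack([RGBAImage.from_uint8(p) for p in pages])
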