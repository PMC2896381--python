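"""Exception types shared across the scene engine."""


class VoxSceneError(Exception):
    """Base class for all package-specific errors."""


class StackFormatError(VoxSceneError):
    """An image stack on disk violates the expected layout.

    Raised for mixed page sizes or depths within one multi-page TIFF and
    for unsupported sample types (RGB pages, floating point, >16-bit).
    """


class InvalidROIError(VoxSceneError, ValueError):
    """A region of interest is unusable for cropping (open, or <3 vertices)."""


class NameCollisionError(VoxSceneError, ValueError):
    """A content or landmark name is already taken within its registry."""


class NotFoundError(VoxSceneError, KeyError):
    """A content or landmark name is not present in its registry."""


class MeshFormatError(VoxSceneError, ValueError):
    """Unknown mesh file format, or a mesh violating structural invariants."""


class OpenMeshError(VoxSceneError, ValueError):
    """Enclosed volume requested for a mesh that is not closed and orientable."""


class LandmarkParseError(VoxSceneError, ValueError):
    """A landmark file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class DegenerateConfigurationError(VoxSceneError, ValueError):
    """Point configuration insufficient for a rigid fit (<3 pairs or collinear)."""


class StateError(VoxSceneError, RuntimeError):
    """Operation issued in the wrong state (recording, playback, editing)."""
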