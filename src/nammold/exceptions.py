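"""Exception hierarchy for nammold.

All errors raised by the library derive from :class:`NammoldError` so callers
(and the CLI) can catch one base class.
"""


class NammoldError(Exception):
    """Base class for all nammold errors."""


class MeshFormatError(NammoldError):
    """Unreadable or truncated mesh file; carries a byte offset when known."""

    def __init__(self, message: str, byte_offset: int | None = None):
        if byte_offset is not None:
            message = f"{message} (at byte offset {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


class EmptyMeshError(NammoldError):
    """Mesh has no vertices or no faces."""


class LandmarkError(NammoldError):
    """Invalid landmark file: unknown/duplicate names or bad coordinates."""


class ParameterError(NammoldError):
    """Invalid parameter combination for a generator or model."""


class FrameError(NammoldError):
    """Occlusal-frame estimation failed (degenerate geometry)."""


class DetectionError(NammoldError):
    """Crest detection failed (too few populated bins, etc.)."""


class FitError(NammoldError):
    """Conic fit failed: too few points, collinear data, or no ellipse."""


class BuildError(NammoldError):
    """Plate construction failed (offset collapse, bad regions, ...)."""


class PlacementError(BuildError):
    """Pin or ventilation-hole position does not intersect the plate."""


class StatsError(NammoldError):
    """Degenerate data or unsupported mode in a statistical test."""
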