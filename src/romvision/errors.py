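"""Exception hierarchy for romvision.

All package errors derive from :class:`RomVisionError` so callers can catch
one base type at pipeline boundaries.
"""


class RomVisionError(Exception):
    """Base class for all romvision errors."""


class InvalidDepthError(RomVisionError):
    """Depth value is non-positive or non-finite where a valid range is required."""


class BehindCameraError(RomVisionError):
    """A 3-D point with Z <= 0 cannot be projected."""


class ConvergenceError(RomVisionError):
    """Iterative undistortion failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ConfigurationError(RomVisionError):
    """Inconsistent configuration (dimension mismatch, invalid window, ...)."""


class MarkerLostError(RomVisionError):
    """A required marker role could not be found in a frame."""

    def __init__(self, role: str, frame_index: int | None = None):
        msg = f"marker '{role}' lost"
        if frame_index is not None:
            msg += f" at frame {frame_index}"
        super().__init__(msg)
        self.role = role
        self.frame_index = frame_index


class InsufficientDepthError(RomVisionError):
    """Too few marker pixels carry valid depth for a stable fit."""


class DegenerateGeometryError(RomVisionError):
    """Point set is degenerate for the requested fit (collinear, identical, ...)."""


class NoValidDataError(RomVisionError):
    """An angle channel contains no valid samples."""


class EmptyInputError(RomVisionError):
    """An operation received an empty frame sequence or point set."""


class GenerationError(RomVisionError):
    """Synthetic scene generation failed (invalid config or visibility)."""
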