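"""Typed exceptions shared across the package.

All failures raised by sctqa derive from :class:`SctqaError` so callers can
catch package errors without swallowing programming mistakes.
"""


class SctqaError(Exception):
    """Base class for all sctqa errors."""


class GridMismatchError(SctqaError):
    """Two structures live on incompatible voxel grids."""

    def __init__(self, frame_a: str, frame_b: str, detail: str = "") -> None:
        msg = f"incompatible grids (frame {frame_a!r} vs {frame_b!r})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)
        self.frame_a = frame_a
        self.frame_b = frame_b


class RegistrationRequiredError(SctqaError):
    """Resampling was requested across frames of reference.

    This package never registers images; inputs must be co-registered
    upstream so that grids with different spacing still share a frame.
    """


class UndefinedMetricError(SctqaError):
    """A metric was requested on input for which it is not defined
    (for example a surface distance involving an empty mask)."""


class EmptyResultError(SctqaError):
    """An auto-contouring step produced an empty segmentation."""


class ValidationError(SctqaError, ValueError):
    """Invalid parameter or malformed input value."""


class MaskIOError(SctqaError, IOError):
    """A structure or volume file could not be read as expected
    (wrong dimensionality, non-binary mask values, unusable header)."""
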