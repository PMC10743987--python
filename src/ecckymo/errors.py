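"""Exception types shared across the package."""


class EcckymoError(Exception):
    """Base class for all package-specific errors."""


class SidecarError(EcckymoError):
    """A required metadata field is missing or invalid in a sidecar file."""


class ChannelCountError(EcckymoError):
    """An image file does not contain exactly three channels."""


class ThresholdError(EcckymoError):
    """Automatic threshold selection is not possible on this image."""


class BaselineError(EcckymoError):
    """The baseline window is too short or overlaps the first rise."""


class RunRejected(EcckymoError):
    """A whole imaging run failed quality control.

    ``reason_code`` is machine readable: ``no_cell``,
    ``too_many_invalid_lines``, ``no_transient`` or ``no_contraction``.
    """

    def __init__(self, reason_code: str, message: str = ""):
        self.reason_code = reason_code
        super().__init__(message or reason_code)
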