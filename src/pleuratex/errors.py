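"""Exception hierarchy.

All user-facing failures derive from :class:`PleuratexError` so the CLI can
map them to exit codes (validation errors -> 1, everything else -> 2).
"""


class PleuratexError(Exception):
    """Base class for all package errors."""


class ValidationError(PleuratexError, ValueError):
    """Invalid input value, shape, or configuration."""


class EmptyRoiError(ValidationError):
    """An ROI admits no co-occurring pixel pair for the requested offset."""


class UnsupportedFormatError(PleuratexError, IOError):
    """Readable file, but in a pixel format the analysis does not support."""
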