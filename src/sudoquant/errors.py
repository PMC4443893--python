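"""Exception hierarchy.

The CLI maps these onto exit codes: ConfigError -> 2, InputError -> 3,
DegenerateDataError (and subclasses) -> 4.
"""


class SudoquantError(Exception):
    """Base class for all package errors."""


class ConfigError(SudoquantError):
    """Invalid or inconsistent configuration (bad key, bad value, bad schema)."""


class InputError(SudoquantError):
    """Unreadable, malformed or unsupported input data (files, arrays)."""


class UnsupportedImageError(InputError):
    """Image decodes but is not usable (e.g. single-channel greyscale)."""


class DegenerateDataError(SudoquantError):
    """Data is structurally valid but degenerate for the requested operation."""


class SegmentationFailure(DegenerateDataError):
    """No plausible pad foreground was found in the scan."""


class EmptyRegionError(DegenerateDataError):
    """An operation that needs a non-empty pixel region received an empty mask."""


class MissingDataError(DegenerateDataError):
    """A required per-subject measurement is absent."""


class InsufficientDataError(DegenerateDataError):
    """Too few observations to compute the requested statistic."""


class DegenerateLabelsError(DegenerateDataError):
    """Binary labels contain only one class."""
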