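"""Exception hierarchy shared by all stations."""


class CocoonSortError(Exception):
    """Base class for all package errors."""


class ValidationError(CocoonSortError):
    """Invalid input data or configuration (CLI exit code 2)."""


class DegenerateImageError(CocoonSortError):
    """Image has no usable contrast (e.g. constant edge map)."""


class NoObjectError(CocoonSortError):
    """A binary mask contains no foreground object."""


class DigitizationError(CocoonSortError):
    """Outline digitization failed (e.g. centroid outside the region)."""


class AlignmentError(CocoonSortError):
    """Procrustes alignment cannot proceed (degenerate shape)."""


class StandardizationError(CocoonSortError):
    """A feature column cannot be Z-scored (zero variance)."""


class PairingError(CocoonSortError):
    """Two per-view results do not belong to the same cocoon."""


class SensorFormatError(ValidationError):
    """Malformed photodiode CSV row."""


class SensorRangeError(ValidationError):
    """ADC count outside the 10-bit range [0, 1023]."""


class SpecError(ValidationError):
    """Invalid synthetic-cocoon specification."""
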