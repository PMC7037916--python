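"""Exception hierarchy used across the package."""


class DuotoxError(Exception):
    """Base class for all package errors."""


class FixtureIntegrityError(DuotoxError):
    """Packaged dataset failed an integrity check."""


class InputError(DuotoxError):
    """User-supplied input could not be used (empty, unparsable, wrong schema)."""


class UsageError(DuotoxError):
    """The caller asked for something the API does not support."""


class CalibrationError(DuotoxError):
    """Composite-index standards could not be calibrated."""


class PreparationError(DuotoxError):
    """3D structure preparation failed for a molecule."""


class AlignmentError(DuotoxError):
    """Template superposition failed (e.g. common scaffold too small)."""


class ConfigurationError(DuotoxError):
    """A configuration combination left nothing to compute."""
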