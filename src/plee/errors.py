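"""Exception hierarchy for the plee package.

All domain errors derive from :class:`PleeError` so batch drivers can catch
one base class while letting programming errors propagate.
"""


class PleeError(Exception):
    """Base class for all plee domain errors."""


class FormatError(PleeError):
    """The file does not look like the expected dialect (missing header,
    missing columns, ...)."""


class ParseError(PleeError):
    """A cell could not be converted to a number, or a sample breaks the
    uniform time grid.  Carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class EmptyRecordingError(PleeError):
    """A signal file with a valid header but no data rows."""


class ValidationError(PleeError):
    """A table or recording violates one of its invariants."""


class EmptyWindowError(PleeError):
    """Trimming to the experiment window removed every sample."""


class NoEndExpirationError(PleeError):
    """No sample passed the end-expiratory (PEEP window AND low-flow) filter."""


class NoPlateauError(PleeError):
    """No sample passed the inspiratory-plateau filter."""


class NoOcclusionSwingError(PleeError):
    """Airway-pressure swing too small to evaluate the occlusion ratio."""


class EstimationFailedError(PleeError):
    """No convincing cardiac spectral peak; caller must supply the heart rate."""


class ConfigError(PleeError):
    """Inconsistent or physically impossible configuration values."""
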