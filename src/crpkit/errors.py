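"""Exception hierarchy for crpkit.

Every error raised by the library derives from :class:`CrpkitError` so
callers can catch pipeline failures without masking programming errors.
"""


class CrpkitError(Exception):
    """Base class for all crpkit errors."""


class FormatError(CrpkitError):
    """A file or table does not match the expected layout."""


class SamplingError(CrpkitError):
    """Time vector is non-uniform or inconsistent with the stated rate."""


class ConfigurationError(CrpkitError):
    """Invalid or unknown run-configuration values."""


class FilterError(CrpkitError):
    """Input too short (or otherwise unusable) for the low-pass filter."""


class EventDetectionError(CrpkitError):
    """No foot-contact events could be detected from the force signal."""


class InsufficientCyclesError(EventDetectionError):
    """A gait trial does not contain two initial contacts (one full cycle)."""


class EventOrderingError(CrpkitError):
    """Detected events are not in the order the task requires."""


class InterpolationError(CrpkitError):
    """Span too short for time normalisation."""


class DegenerateGeometryError(CrpkitError):
    """Coincident markers: segment direction undefined."""


class DegenerateSignalError(CrpkitError):
    """Constant signal: amplitude normalisation undefined."""


class UndefinedPhaseError(CrpkitError):
    """Phase angle undefined at the first sample (both coordinates zero)."""
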