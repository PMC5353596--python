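"""Exception hierarchy.

All package errors derive from :class:`PhenolinkError` so callers can catch
one base class; subclasses distinguish bad configuration from bad data from
failed numerical extraction.
"""


class PhenolinkError(Exception):
    """Base class for all errors raised by phenolink."""


class ConfigurationError(PhenolinkError):
    """A parameter or configuration value violates its contract."""


class DataError(PhenolinkError):
    """Input data violate a structural or numerical precondition."""


class CalibrationError(PhenolinkError):
    """Sensor calibration inputs are inconsistent or degenerate."""


class ExtractionError(PhenolinkError):
    """An OCR value could not be extracted from a trace."""
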