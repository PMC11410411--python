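"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigurationError -> 2,
DataQualityError (and subclasses) -> 3, everything else -> 1.
"""


class GaitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaitError):
    """Invalid configuration value, unknown key, or unusable parameter."""


class DomainError(GaitError):
    """Argument outside its mathematical domain (e.g. fraction not in [0, 1])."""


class FormatError(GaitError):
    """File does not conform to a supported dialect (missing marker, bad header)."""


class UnsupportedFormatError(FormatError):
    """Requested file format is not available in this installation."""


class DataQualityError(GaitError):
    """Data is syntactically valid but unusable (long gaps, degenerate segments)."""


class TrialTooShortError(DataQualityError):
    """Fewer than two same-side foot contacts: no complete gait cycle."""


class MissingDataError(GaitError):
    """A participant/condition cell required by the statistics is empty."""
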