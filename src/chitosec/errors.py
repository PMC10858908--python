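"""Exception hierarchy.

All package-specific failures derive from :class:`ChitosecError` so callers
(and the CLI) can distinguish bad inputs/configuration (exit code 2) from
runtime failures (exit code 1).
"""


class ChitosecError(Exception):
    """Base class for all chitosec errors."""


class ValidationError(ChitosecError):
    """Input data violates a documented invariant."""


class FormatError(ValidationError):
    """A file could not be parsed as the expected format."""


class ConfigurationError(ValidationError):
    """Parameters or rule tables are inconsistent or incomplete."""


class ParameterError(ValidationError):
    """A numeric parameter is out of its admissible range."""


class FitError(ChitosecError):
    """A regression segment could not be fitted."""


class NoPeakError(ChitosecError):
    """No peak found where one is required (e.g. all-zero polymer region)."""


class NoPolymerError(ChitosecError):
    """Polymer statistics requested on an empty polymer pool."""


class UndefinedShareError(ChitosecError):
    """Fraction of an all-zero total is undefined."""


class UndefinedFAError(ChitosecError):
    """Average acetylation of an empty oligomer pool is undefined."""
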