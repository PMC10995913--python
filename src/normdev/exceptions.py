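"""Exception hierarchy for normdev.

Every error raised on purpose by this package derives from
:class:`NormdevError`, so callers can catch one base class at a pipeline
boundary while still distinguishing configuration mistakes from data
problems where it matters.
"""


class NormdevError(Exception):
    """Base class for all errors raised by normdev."""


class ConfigurationError(NormdevError, ValueError):
    """A simulation or run configuration field is invalid."""


class ParameterError(NormdevError, ValueError):
    """A function argument is outside its admissible range."""


class DataError(NormdevError, ValueError):
    """Input data violate a contract (non-finite values, bad shapes)."""


class FittingError(NormdevError, RuntimeError):
    """The reference fit cannot proceed (too few controls, degenerate design)."""


class CalibrationError(NormdevError, RuntimeError):
    """Site recalibration failed or is missing for a requested site."""


class ValidationError(NormdevError, ValueError):
    """A table or file failed schema validation."""


class ParseError(NormdevError, ValueError):
    """A FreeSurfer stats file could not be parsed."""


class SingularityError(NormdevError, ValueError):
    """A regression design matrix is rank deficient."""
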