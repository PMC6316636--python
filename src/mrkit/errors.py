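"""Exception hierarchy shared across mrkit modules."""


class MrkitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MrkitError):
    """Invalid user configuration (bad column map, bad parameter value)."""


class ParseError(MrkitError):
    """A data file could not be parsed; the message names the row."""


class ValidationError(MrkitError):
    """A record violates a domain invariant (e.g. se <= 0)."""


class HarmonizationError(MrkitError):
    """Exposure/outcome records cannot be reconciled (strict mode)."""


class InsufficientInstrumentsError(MrkitError):
    """An estimator was given fewer SNPs than its minimum."""


class OrientationError(MrkitError):
    """Instruments are not oriented as the estimator requires."""


class UndefinedRatioError(MrkitError):
    """Wald ratio undefined: the SNP-exposure effect is zero."""


class BoundExceededError(MrkitError):
    """A numerical search left its bracket (e.g. detectable OR > 10)."""
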