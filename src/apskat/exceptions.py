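"""Exception hierarchy for apskat."""


class ApskatError(Exception):
    """Base class for all apskat errors."""


class FormatError(ApskatError):
    """A file is not in the expected on-disk format (bad magic bytes, wrong mode)."""


class DimensionError(ApskatError):
    """Array or file dimensions are mutually inconsistent."""


class ParseError(ApskatError):
    """A text table could not be parsed; carries row/column context in the message."""


class ConfigurationError(ApskatError):
    """A stopping or simulation configuration violates its constraints."""


class ConvergenceError(ApskatError):
    """The null-model fit failed to converge (e.g. separation in a logistic fit)."""


class CollinearityError(ApskatError):
    """The covariate design matrix is rank deficient."""
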