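"""Exception hierarchy shared across the package."""


class EvCompareError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EvCompareError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(EvCompareError, ValueError):
    """Invalid or inconsistent configuration / input description."""


class FitError(EvCompareError, RuntimeError):
    """A model fit diverged or produced a degenerate result."""


class SaturatedArrayError(DomainError):
    """Every counted well is 'on'; the digital readout carries no information."""
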