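"""Exception hierarchy shared across the pipeline."""


class TrapshiftError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(TrapshiftError):
    """A file does not conform to its expected on-disk format."""


class ValidationError(TrapshiftError):
    """Parsed data violates a structural invariant (duplicates, bad labels, ...)."""


class NormalizationError(TrapshiftError):
    """A normalization step cannot be computed (e.g. no reference genes)."""


class DesignError(TrapshiftError):
    """The experimental design is unusable (rank deficient, too few pairs, ...)."""


class ConfigError(TrapshiftError):
    """A run or simulation configuration is invalid."""
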