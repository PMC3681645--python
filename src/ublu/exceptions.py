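"""Exception hierarchy for the package."""


class UnmixError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(UnmixError):
    """A delimited-text file could not be parsed into a numeric matrix."""


class ConstraintError(UnmixError):
    """A model constraint (non-negativity, simplex, shapes) is violated."""


class DimensionError(UnmixError):
    """A requested dimension is incompatible with the data (e.g. rank deficiency)."""


class ConfigError(UnmixError):
    """An invalid run configuration."""
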