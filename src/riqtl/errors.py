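"""Exception hierarchy shared across the pipeline."""


class RiqtlError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(RiqtlError, ValueError):
    """Invalid simulation or run configuration."""


class ParseError(RiqtlError, ValueError):
    """A file failed structural validation; message lists offending rows."""


class SchemaError(RiqtlError, ValueError):
    """Mandatory column or header missing from an input table."""


class AlignmentError(RiqtlError, ValueError):
    """Strain (or gene) id sets across inputs have an empty intersection."""


class InputError(RiqtlError, ValueError):
    """Non-finite or otherwise unusable values in an input vector."""


class DegenerateInputError(RiqtlError, ValueError):
    """An operation received an input with no usable signal (e.g. zero markers)."""


class EmptyScanError(RiqtlError, ValueError):
    """Every marker was removed by filtering; no scan statistics exist."""


class DomainError(RiqtlError, ValueError):
    """A numeric argument is outside the mathematical domain of the operation."""
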