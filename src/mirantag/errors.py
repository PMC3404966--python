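"""Exception types shared across the package."""


class MirantagError(Exception):
    """Base class for package-specific errors."""


class DegenerateInputError(MirantagError, ValueError):
    """A vector is constant or too short for the requested statistic."""


class SchemaError(MirantagError, ValueError):
    """Input tables do not satisfy the structural contract (sample mismatch, empty matrix, ...)."""


class ParseError(MirantagError, ValueError):
    """A file could not be parsed; the message names the offending cell."""
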