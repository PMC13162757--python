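"""Exception hierarchy shared across the package."""


class SalametError(Exception):
    """Base class for all package errors."""


class ConfigError(SalametError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class ParseError(SalametError, ValueError):
    """An input file could not be parsed into a valid in-memory object."""


class ValidationError(SalametError, ValueError):
    """An in-memory object violates a structural invariant."""
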