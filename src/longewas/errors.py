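"""Exception hierarchy shared across the pipeline stages."""


class LongewasError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LongewasError, ValueError):
    """A configuration object violates one of its invariants."""


class ValidationError(LongewasError, ValueError):
    """An input value or container violates a documented precondition."""


class DataError(LongewasError, ValueError):
    """Inconsistent data passed between pipeline stages (shape/id mismatches)."""
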