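"""Exception hierarchy for the AP-MS profiling pipeline."""


class ApmsError(Exception):
    """Base class for all package errors."""


class FormatError(ApmsError):
    """A file does not conform to the documented tabular dialect."""


class ValidationError(ApmsError):
    """Data violate an invariant (negative counts, duplicate cells, ...)."""


class ConfigError(ApmsError):
    """A configuration is incomplete or inconsistent."""


class DataError(ApmsError):
    """Input data are degenerate for the requested operation."""


class DependencyError(ApmsError):
    """A pipeline stage's recorded inputs or outputs no longer match on disk."""
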