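"""Exception types shared across the package."""


class EsmError(Exception):
    """Base class for package errors."""


class SchemaError(EsmError):
    """Input table does not provide the required columns/types."""


class IntegrityError(EsmError):
    """Input violates a structural invariant (e.g. duplicated beeps)."""


class ConfigurationError(EsmError):
    """A configuration object is internally inconsistent."""


class EstimationError(EsmError):
    """Model estimation failed (rank deficiency, non-convergence)."""
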