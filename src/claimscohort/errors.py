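"""Exception types shared across the package."""


class ClaimsCohortError(Exception):
    """Base class for package errors."""


class ConfigurationError(ClaimsCohortError):
    """A configuration file or simulation spec is missing or inconsistent."""


class ValidationError(ClaimsCohortError):
    """Data or derived quantities violate a stated invariant."""


class SchemaError(ClaimsCohortError):
    """An input table is missing required columns or files."""
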