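"""Exception hierarchy shared across the package."""


class MlcQsarError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MlcQsarError):
    """Input table does not match the expected column schema."""


class ParseError(MlcQsarError):
    """A cell could not be parsed as the declared type."""


class ValidationError(MlcQsarError):
    """Parsed values violate a table or type invariant."""


class SingularFitError(MlcQsarError):
    """Design matrix is rank deficient or has zero variance."""


class DescriptorUndefinedError(MlcQsarError):
    """A derived descriptor is undefined (e.g. log of a non-positive slope)."""


class DegenerateLeverageError(MlcQsarError):
    """A leave-one-out residual is undefined because a leverage equals 1."""


class ConfigError(MlcQsarError):
    """Invalid generator or pipeline configuration."""
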