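"""Exception hierarchy shared across the package."""


class HatchrankError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HatchrankError, ValueError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(HatchrankError, ValueError):
    """A row or value violates a data invariant (e.g. winner == loser)."""


class ConfigurationError(HatchrankError, ValueError):
    """A parameter or configuration value is inconsistent or out of range."""
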