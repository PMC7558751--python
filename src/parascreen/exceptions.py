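"""Exception hierarchy shared across the package."""


class ParascreenError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ParascreenError):
    """A table is structurally invalid (missing columns, duplicate keys,
    missing plasmid sample, ...)."""


class ConfigError(ParascreenError):
    """A parameter or specification value is unusable (empty guide pool,
    non-positive depth, gene missing from the fitness map, ...)."""


class DegenerateDistributionError(ParascreenError):
    """A distribution required for standardization has zero spread."""
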