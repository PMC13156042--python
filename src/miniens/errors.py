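"""Exception hierarchy shared across the package."""


class MiniensError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MiniensError, ValueError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(MiniensError, ValueError):
    """Input data violate a precondition of an operation."""


class CapacityError(MiniensError, RuntimeError):
    """Spatial placement could not satisfy the separation constraint."""


class SchemaError(MiniensError, ValueError):
    """A session container or table fails schema validation."""
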