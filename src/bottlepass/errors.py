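"""Exception types shared across the package."""


class BottlepassError(Exception):
    """Base class for package errors."""


class DomainError(BottlepassError, ValueError):
    """A numerical argument is outside the domain of the operation."""


class SchemaError(BottlepassError, ValueError):
    """A tabular input does not conform to the expected schema."""


class UsageError(BottlepassError, ValueError):
    """An operation was invoked with structurally invalid inputs (e.g. empty axes)."""
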