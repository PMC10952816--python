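"""Exception types shared across the package."""


class MsamError(Exception):
    """Base class for package errors."""


class SchemaError(MsamError, ValueError):
    """An input table is missing required columns or has a malformed layout."""


class ValidationError(MsamError, ValueError):
    """A value violates a domain invariant (negative count, bad probability...)."""


class ConvergenceError(MsamError, RuntimeError):
    """The sampler could not be initialised at a finite log posterior."""
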