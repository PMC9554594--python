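"""Exception types shared across the package."""


class RhizopipeError(Exception):
    """Base class for all package errors."""


class ValidationError(RhizopipeError, ValueError):
    """Raised when an input violates an operation's preconditions."""


class DegenerateInputError(RhizopipeError, ValueError):
    """Raised when a quantity is undefined on the given input (e.g. empty denominator)."""
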