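"""Exception hierarchy shared across the package."""


class ReclineError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ReclineError, ValueError):
    """Invalid input: bad shapes, unknown labels, violated preconditions."""


class ParseError(ReclineError, ValueError):
    """Malformed on-disk data (non-numeric cells, missing columns)."""


class DegenerateInputError(ReclineError, ValueError):
    """Numerically degenerate input (e.g. all-zero signal)."""


class TrainingError(ReclineError, RuntimeError):
    """Model training failed (e.g. divergent loss)."""
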