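"""Exception hierarchy shared across the package.

Validation failures (bad inputs, malformed files, impossible scenarios) and
fit failures (non-convergence, unidentifiable parameters) are distinguished
so the command-line layer can map them to distinct exit codes.
"""


class NanokinError(Exception):
    """Base class for all package errors."""


class ValidationError(NanokinError):
    """An input violated a documented precondition or invariant."""


class DegenerateInputError(ValidationError):
    """Input is syntactically valid but degenerate (e.g. zero initial turbidity)."""


class FitError(NanokinError):
    """A model fit could not be carried out or is unidentifiable."""


def require(condition: bool, field: str, message: str) -> None:
    """Raise :class:`ValidationError` naming the offending field."""
    if not condition:
        raise ValidationError(f"{field}: {message}")
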