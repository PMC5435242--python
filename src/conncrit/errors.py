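"""Exception hierarchy for conncrit.

All package-specific failures derive from :class:`ConncritError` so callers
can catch one base class at pipeline boundaries.
"""


class ConncritError(Exception):
    """Base class for all conncrit errors."""


class ConfigurationError(ConncritError):
    """A configuration record is inconsistent (bad model name, bad field value)."""


class ValidationError(ConncritError):
    """An input object violates a structural invariant (asymmetry, bad shape)."""


class MatrixParseError(ConncritError):
    """A matrix text file could not be parsed (non-square, non-numeric, empty)."""


class ParameterError(ConncritError):
    """Distribution parameters are outside the admissible region."""


class InsufficientDataError(ConncritError):
    """Too few usable observations to fit a model."""


class DegenerateSampleError(ConncritError):
    """A sample is degenerate (all values equal) so the estimator diverges."""


class FitConvergenceError(ConncritError):
    """Numerical optimisation of a likelihood failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
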