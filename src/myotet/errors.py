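"""Exception hierarchy.

``ValidationError`` covers malformed inputs and violated parameter
invariants (CLI exit code 2); ``NumericalError`` covers optimizer and
degenerate-computation failures (CLI exit code 3).
"""


class MyotetError(Exception):
    """Base class for all package errors."""


class ValidationError(MyotetError, ValueError):
    """Invalid input data or violated domain invariant."""


class ParameterError(ValidationError):
    """A twitch/motor-unit parameter violates its ordering or sign invariant."""


class GridMismatchError(ValidationError):
    """Two force traces do not share the same sampling grid."""


class NumericalError(MyotetError, RuntimeError):
    """A numerical procedure failed to produce a usable result."""


class FitConvergenceError(NumericalError):
    """Least-squares twitch fitting diverged or stalled."""


class DegenerateFitError(NumericalError):
    """The data contain no signal to fit (e.g. an all-zero residual)."""
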