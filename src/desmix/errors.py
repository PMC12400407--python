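"""Exception hierarchy shared across analysis stages."""


class DesmixError(Exception):
    """Base class for all package errors."""


class DomainError(DesmixError, ValueError):
    """An input violates a documented precondition (bad fraction, cutoff, ...)."""


class PlacementError(DesmixError, RuntimeError):
    """Particle insertion could not satisfy the minimum-distance constraint."""


class IntegrationError(DesmixError, RuntimeError):
    """The integrator produced an unphysical step (blow-up)."""


class UnwrapError(DesmixError, RuntimeError):
    """Periodic unwrapping is ambiguous (inter-frame jump beyond half box)."""


class UndefinedMetricError(DesmixError, ArithmeticError):
    """A ratio metric has a zero denominator; distinct from a value of 0."""


class InsufficientDataError(DesmixError, RuntimeError):
    """Not enough frames, members or grid points to compute the estimate."""


class FitError(DesmixError, RuntimeError):
    """A regression could not be carried out on the supplied window."""


class ParseError(DesmixError, ValueError):
    """A structure/trajectory file failed to parse; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
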