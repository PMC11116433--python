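"""Exception hierarchy.

Everything is a ``ValueError`` subclass so callers that don't care about the
fine distinction can catch one type; the CLI maps :class:`TadHierError` to
exit status 2 (data error) and leaves genuine usage errors to the parser.
"""


class TadHierError(ValueError):
    """Base class for all data-level errors raised by tadhier."""


class GridError(TadHierError):
    """A coordinate is not a multiple of the resolution."""


class IntervalError(TadHierError):
    """An interval has end <= start."""


class BoundsError(TadHierError):
    """A coordinate or bin index lies outside the chromosome."""


class ParameterError(TadHierError):
    """An operation parameter is out of its admissible range."""


class ParseError(TadHierError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ShapeError(TadHierError):
    """Matrix shapes are inconsistent."""


class SymmetryError(TadHierError):
    """A matrix that must be symmetric is not."""


class ResolutionError(TadHierError):
    """Two objects that must share a resolution do not."""


class DegenerateInputError(TadHierError):
    """The input is structurally empty (e.g. every bin masked)."""
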