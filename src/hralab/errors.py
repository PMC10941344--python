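"""Exception hierarchy shared across hralab modules."""


class HRALabError(Exception):
    """Base class for all hralab-specific errors."""


class ParseError(HRALabError, ValueError):
    """A text input could not be parsed; the message names the offending line."""


class EmptyInputError(ParseError):
    """An input stream contained no numeric records."""


class SchemaError(HRALabError, ValueError):
    """Metric rows do not share a common key set."""


class InsufficientDataError(HRALabError, ValueError):
    """A series is too short for the requested operation."""


class DegenerateInputError(HRALabError, ValueError):
    """The operation is undefined on this input (e.g. a constant series)."""


class QualityError(HRALabError):
    """A recording failed a quality gate (too many artifacted beats)."""


class UndefinedIndexError(HRALabError):
    """An asymmetry index is undefined (e.g. every Poincare pair is neutral)."""


class UndefinedCorrelationError(HRALabError):
    """Correlation undefined because one variable is constant."""


class WindowBoundsError(HRALabError, ValueError):
    """A requested analysis window extends beyond the recording."""


class CohortSizeError(HRALabError):
    """Fewer complete subjects than the cohort analysis requires."""


class GenerationError(HRALabError):
    """The synthetic generator produced an invalid beat."""
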