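"""Exception hierarchy for the pipeline."""


class CallometryError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CallometryError):
    """Unreadable or unsupported input file."""


class DegenerateInputError(CallometryError):
    """Input too short, empty, or constant for the requested operation."""


class InsufficientDataError(CallometryError):
    """Fewer observations than the operation requires."""


class ConsistencyError(CallometryError):
    """Inputs that contradict each other (e.g. out-of-range segment)."""


class ParameterError(CallometryError):
    """Parameter outside its admissible range."""


class TreeError(CallometryError):
    """Invalid phylogeny (negative branch lengths, name mismatches...)."""


class NumericalError(CallometryError):
    """Singular matrix or failed optimisation."""
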