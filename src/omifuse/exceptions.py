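"""Exception hierarchy for omifuse."""


class OmifuseError(Exception):
    """Base class for all omifuse errors."""


class InvalidSpecError(OmifuseError, ValueError):
    """A generator or training spec violates its invariants."""


class EmptyMatrixError(OmifuseError, ValueError):
    """An operation left (or was handed) a matrix with no usable features."""


class DegenerateClassError(OmifuseError, ValueError):
    """A class has too few samples for the requested statistic or fit."""


class DomainError(OmifuseError, ValueError):
    """Values are outside the domain an operation needs (e.g. log of <= 0)."""


class OrderMismatchError(OmifuseError, ValueError):
    """Class or modality orders of two objects disagree."""


class NoInformationError(OmifuseError, ValueError):
    """A sample has no available modality, so no prediction is possible."""
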