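"""Exception hierarchy for dancedsp."""


class DanceDSPError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DanceDSPError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateCounterbalanceError(InvalidInputError):
    """Two entries of a counterbalance set coincide."""


class IncompleteTrialError(DanceDSPError):
    """A Go trial has fewer responses than the sequence length."""


class EmptySummaryError(DanceDSPError):
    """A summary was requested over zero completed trials."""


class FormatError(DanceDSPError):
    """A recording container could not be parsed."""
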