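"""Exception hierarchy shared by all asmrefine modules."""


class AsmRefineError(Exception):
    """Base class for all toolkit errors."""


class EmptySpectrumError(AsmRefineError):
    """Raised when k-mer counting yields no countable k-mers."""


class NoSignalError(AsmRefineError):
    """Raised when a histogram has no detectable peak structure."""


class InsufficientDataError(AsmRefineError):
    """Raised when too few usable records are available for an estimate."""


class ReferenceMismatchError(AsmRefineError):
    """Raised when alignments reference sequences absent from the assembly."""


class CoordinateError(AsmRefineError):
    """Raised for intervals that fall outside their sequence."""


class InputError(AsmRefineError):
    """Raised for malformed or inconsistent user input."""
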