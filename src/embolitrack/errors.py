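"""Exception hierarchy for the embolitrack pipeline."""


class EmboliTrackError(Exception):
    """Base class for all embolitrack errors."""


class InputError(EmboliTrackError):
    """A required input (path, file) is missing or unreadable."""


class FormatError(EmboliTrackError):
    """Input data violate a format contract (shape mismatch, empty stack, ...)."""


class DegenerateInputError(EmboliTrackError):
    """Input is formally valid but carries no usable signal (e.g. fully saturated ROI)."""


class UndefinedStatisticError(EmboliTrackError):
    """A statistic is requested on a sample where it is undefined (n < 2, zero variance)."""
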