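"""Exception hierarchy shared by all ratecon stages."""


class RateconError(Exception):
    """Base class for all ratecon errors."""


class InvalidArgumentError(RateconError, ValueError):
    """An argument violates a documented precondition."""


class AlignmentFormatError(RateconError):
    """Malformed alignment input (ragged rows, duplicate labels, ...)."""


class TreeFormatError(RateconError):
    """Malformed or unsupported tree input (unrooted, polytomous, ...)."""


class UndefinedDistanceError(RateconError):
    """A pairwise distance has no comparable sites."""


class DegenerateModelError(RateconError):
    """Model estimation attempted on data with no signal."""


class DegenerateFrequenciesError(RateconError):
    """Base frequencies leave the full-saturation entropy undefined."""


class InvalidCladeError(RateconError):
    """A named clade does not resolve to a monophyletic tip set."""


class InvalidStateError(RateconError):
    """Operation requires state (e.g. branch rates) that is missing."""


class ConstraintError(RateconError):
    """Topology constraints are inconsistent or unsupported."""
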