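"""Exception hierarchy for km2ipd."""


class KM2IPDError(Exception):
    """Base class for all km2ipd errors."""


class ParseError(KM2IPDError):
    """A CSV cell could not be interpreted; the message names the row."""


class InsufficientDataError(KM2IPDError):
    """Fewer usable rows/records than the operation requires."""


class ValidationError(KM2IPDError):
    """A domain invariant is violated (event flags, risk-table shape, labels)."""


class ReconstructionInfeasibleError(KM2IPDError):
    """The curve and risk table cannot be reconciled; the message names the interval."""


class ExtrapolationError(KM2IPDError):
    """A truncation time lies beyond the observed follow-up; refusing to extrapolate."""
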