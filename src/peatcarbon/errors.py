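"""Exception hierarchy for the peatcarbon package."""


class PeatCarbonError(Exception):
    """Base class for all peatcarbon errors."""


class ParseError(PeatCarbonError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PeatCarbonError):
    """An in-memory table violates one of its structural invariants."""


class CoverageError(PeatCarbonError):
    """A calibration curve does not cover the posterior support of a date."""


class ChronologyError(PeatCarbonError):
    """Age-depth modelling failed (e.g. too many age reversals)."""


class OutOfSpanError(PeatCarbonError):
    """A requested age or depth lies outside the modelled span."""
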