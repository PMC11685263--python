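"""Exception hierarchy for tmcsim."""


class TMCError(Exception):
    """Base class for all tmcsim errors."""


class ConfigurationError(TMCError, ValueError):
    """A study configuration or operation argument is invalid."""


class DomainError(TMCError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class FeasibilityError(TMCError, ValueError):
    """The requested condition cannot generate a unit-variance outcome."""


class CollinearityError(TMCError, ValueError):
    """A regression design matrix is rank deficient (or a 2x2 system singular)."""


class DegenerateDataError(TMCError, ValueError):
    """Input data carry no usable variation (e.g. zero pooled variance)."""


class ReportError(TMCError, ValueError):
    """A report was requested from empty or unmatched summaries."""
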