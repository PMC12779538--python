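"""Exception hierarchy."""


class VisitCarbonError(Exception):
    """Base class for all package errors."""


class InvalidInputError(VisitCarbonError, ValueError):
    """A value violates an operation's precondition (negative distance, bad share...)."""


class ValidationError(VisitCarbonError, ValueError):
    """A table or config fails schema/invariant validation."""


class ConfigurationError(VisitCarbonError, ValueError):
    """Inconsistent reference data, e.g. flying requested for a city with no airport."""
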