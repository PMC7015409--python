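"""Shared exception types.

All are ``ValueError`` subclasses so callers that only care about "bad input"
can catch one base class.
"""


class PhytoshelfError(ValueError):
    """Base class for all phytoshelf errors."""


class InsufficientDataError(PhytoshelfError):
    """Too few points / levels / replicates for the requested operation."""


class RankDeficiencyError(PhytoshelfError):
    """Design matrix is rank deficient (e.g. duplicate x collapsing rank)."""


class NoRealRootsError(PhytoshelfError):
    """Quadratic discriminant is negative; the parabola has no real roots."""


class TransformDomainError(PhytoshelfError):
    """A rate-law linearisation is undefined for the given concentrations."""


class ConfigurationError(PhytoshelfError):
    """Invalid study design, trajectory mapping, or pipeline configuration."""


class ParseError(PhytoshelfError):
    """Malformed assay CSV input; message names the row and field."""
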