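"""Exception hierarchy.

All package errors derive from :class:`VertmorphError` so callers (and the
CLI) can distinguish data problems from programming errors.
"""


class VertmorphError(Exception):
    """Base class for all vertmorph errors."""


class FormatError(VertmorphError):
    """A file does not conform to the expected column layout."""


class IntegrityError(VertmorphError):
    """Duplicate or contradictory rows within one dataset."""


class ParseError(VertmorphError):
    """A value could not be parsed; the message names the offending row."""


class DomainError(VertmorphError):
    """Geometrically degenerate landmarks (zero height/width, coincident points)."""


class MissingReferenceError(VertmorphError):
    """A (region, level, metric) stratum has no usable reference entry."""


class InfeasibleParameterError(VertmorphError):
    """No quadrilateral exists for the requested shape parameters."""


class GeometryError(VertmorphError):
    """Invalid projection geometry (e.g. a corner at or beyond the source plane)."""


class RankDeficiencyError(VertmorphError):
    """The ANOVA design matrix is rank deficient; the message names the term."""
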