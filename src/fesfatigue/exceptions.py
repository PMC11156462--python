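"""Exception hierarchy.

All package errors derive from :class:`FesFatigueError`; most are also
``ValueError`` subclasses so generic callers can catch them idiomatically.
"""


class FesFatigueError(Exception):
    """Base class for all errors raised by fesfatigue."""


class InvalidSpecError(FesFatigueError, ValueError):
    """A synthetic-trial or protocol specification violates its invariants."""


class FormatError(FesFatigueError, ValueError):
    """A signal or table file does not conform to the expected dialect."""


class ParameterError(FesFatigueError, ValueError):
    """An analysis parameter is outside its admissible range."""


class LengthError(FesFatigueError, ValueError):
    """A record is too short for the requested operation."""


class DegenerateCurveError(FesFatigueError, ValueError):
    """A curve is constant where a spread of values is required."""


class ShapeError(FesFatigueError, ValueError):
    """A fitted fatigue curve is not M-shaped.

    Carries the interior critical points that were found so callers can
    diagnose why four-stage decomposition failed.
    """

    def __init__(self, message: str, critical_points=None):
        super().__init__(message)
        self.critical_points = list(critical_points) if critical_points else []


class InsufficientDataError(FesFatigueError, ValueError):
    """Too few points for the requested fit."""


class DomainError(FesFatigueError, ValueError):
    """A value lies outside the mathematical domain of a fitted model."""


class ConfoundedDesignError(FesFatigueError, ValueError):
    """More than one stimulation-protocol field varies within one comparison."""
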