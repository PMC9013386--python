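"""Exception hierarchy for magchip.

Every error raised by the library derives from :class:`MagchipError` so that
callers (and the CLI) can catch library failures without masking genuine bugs.
"""


class MagchipError(Exception):
    """Base class for all magchip errors."""


class InvalidSpecError(MagchipError, ValueError):
    """A geometry/track/bend specification violates its invariants."""


class UnsupportedStyleError(MagchipError, ValueError):
    """Requested bend style is not one of the templated designs."""


class InvalidArgumentError(MagchipError, ValueError):
    """A scalar argument is out of its allowed range."""


class EmptyPatternError(MagchipError, ValueError):
    """An operation that needs magnets received a pattern with none."""


class DomainError(MagchipError, ValueError):
    """A position lies outside the region where a quantity is defined."""


class DegenerateNormalizationError(MagchipError, ValueError):
    """Min-max normalization of a constant array is undefined."""


class SingularSeparationError(MagchipError, ValueError):
    """Two point dipoles coincide; the pair force diverges."""


class NumericalFailureError(MagchipError, RuntimeError):
    """The integrator produced non-finite forces or positions."""


class InsufficientDataError(MagchipError, ValueError):
    """Not enough samples/periods/replicates to compute the statistic."""


class NoTransportError(MagchipError, RuntimeError):
    """No frequency in the sweep produced phase-locked transport."""


class UnbracketedThresholdError(MagchipError, RuntimeError):
    """A design-rule sweep did not straddle the locked/stuck transition."""


class InvalidPatternError(MagchipError, ValueError):
    """A pattern lacks the structure (labels, spine) an operation needs."""


class InvalidInputError(MagchipError, ValueError):
    """An image or dataset input is empty or malformed."""


class InvalidModelError(MagchipError, ValueError):
    """Binding-model parameters violate their constraints."""


class PackingError(MagchipError, RuntimeError):
    """Random non-overlapping placement failed (domain overfilled)."""


class FitFailureError(MagchipError, RuntimeError):
    """Maximum-likelihood fit could not be performed on degenerate data."""


class InvalidSceneError(MagchipError, ValueError):
    """A synthetic chamber scene is inconsistent (beads out of frame, ...)."""
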