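"""Exception hierarchy.

All user-facing failures derive from :class:`GxesimError` so callers (and the
CLI) can catch one type.  Validation problems are ``ValueError`` subclasses.
"""


class GxesimError(Exception):
    """Base class for all package errors."""


class ValidationError(GxesimError, ValueError):
    """A parameter or specification violates its documented invariant."""


class PlacementError(ValidationError):
    """Epistatic cells violate the row/column placement rule."""


class InfeasibleParametersError(GxesimError):
    """The requested epidemiological parameters admit no valid penetrance.

    Carries a human-readable description of the binding constraint.
    """


class ModelInconsistencyError(GxesimError):
    """A G-by-E model was requested that is inconsistent with the target risks."""


class ConvergenceError(GxesimError):
    """A root-find or optimization failed; the message carries diagnostics."""
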