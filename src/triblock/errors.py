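"""Exception hierarchy shared across the package."""


class TriblockError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TriblockError, ValueError):
    """A physical parameter is outside its admissible domain."""


class OverstretchError(TriblockError, FloatingPointError):
    """A FENE bond reached or exceeded its maximum extension R0.

    In practice this identifies an unstable timestep (or a corrupted
    configuration), so the offending pair is reported.
    """


class GeometryError(TriblockError, ValueError):
    """A geometric precondition is violated (e.g. minimum-image ambiguity)."""


class InitializationError(TriblockError, RuntimeError):
    """System construction failed (e.g. packing infeasible after retries)."""


class InstabilityError(TriblockError, RuntimeError):
    """Integration produced non-finite coordinates."""


class ClassificationError(TriblockError, ValueError):
    """A cluster cannot be assigned a shape class (degenerate tensor)."""


class FitError(TriblockError, RuntimeError):
    """A model fit did not converge or the data do not constrain it."""
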