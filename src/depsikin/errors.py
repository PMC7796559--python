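"""Typed exceptions shared across the package."""


class DepsikinError(Exception):
    """Base class for all errors raised by depsikin."""


class SchemaError(DepsikinError):
    """A delimited-text or config input violates the expected schema."""


class DimensionError(DepsikinError):
    """Array/matrix dimensions are inconsistent with the declared network."""


class MatrixLogError(DepsikinError):
    """The principal matrix logarithm of the transfer matrix is not defined.

    Raised when an eigenvalue is non-positive or carries a non-negligible
    imaginary component, which typically signals inconsistent (too noisy)
    peak volumes rather than a numerical problem.
    """


class FitError(DepsikinError):
    """A nonlinear fit failed or was requested with non-identifiable parameters."""


class SpeciationError(DepsikinError):
    """The equilibrium speciation problem is ill-posed for the given model."""
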