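"""Exception hierarchy for vadsim.

All package-specific errors derive from :class:`VadsimError` so callers can
catch the whole family with one clause; most also subclass the closest
built-in (``ValueError`` for bad numeric input, ``KeyError``-like lookups
stay built-in).
"""


class VadsimError(Exception):
    """Base class for all vadsim errors."""


class InvalidDeformationError(VadsimError, ValueError):
    """Deformation gradient is not physical (det F <= 0 or wrong shape)."""


class NormalizationError(VadsimError, ValueError):
    """Reference fiber direction is not a unit vector."""


class ModeError(VadsimError, ValueError):
    """A convenience evaluation mode was requested for an incompatible state."""


class OracleDomainError(VadsimError, ValueError):
    """Numerical-differentiation stencil left the energy function's domain."""


class ConfigurationError(VadsimError, ValueError):
    """Invalid protocol, anatomy, or material configuration value."""


class SchemaError(ConfigurationError):
    """Config file contains unknown or ill-typed keys; lists the offenders."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(f"invalid config entries: {', '.join(self.offenders)}")


class GeometryError(VadsimError, ValueError):
    """Ring or head geometry is inconsistent with the model axis."""


class DataError(VadsimError, ValueError):
    """Experimental-style input curve is empty, degenerate, or non-monotone."""


class OptimizationError(VadsimError, RuntimeError):
    """Least-squares calibration failed to converge; carries the solver trace."""

    def __init__(self, message, trace=None):
        self.trace = trace
        super().__init__(message)


class ComparabilityError(VadsimError, ValueError):
    """Scenario results were produced with different anatomies."""
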