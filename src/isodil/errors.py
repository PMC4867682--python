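"""Exception hierarchy shared across the package."""


class IsodilError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(IsodilError, ValueError):
    """A numeric argument is outside its physical domain."""


class ChronologyError(IsodilError, ValueError):
    """A count date precedes the labeling reference date."""


class DegenerateFitError(IsodilError, ValueError):
    """Too few points or zero predictor variance for a regression."""


class DegenerateReferenceError(IsodilError, ValueError):
    """An unfertilized reference pot has no P left after seed correction."""


class DegenerateSeriesError(IsodilError, ValueError):
    """A kinetics series carries no exchange signal."""


class FitFailureError(IsodilError, RuntimeError):
    """Nonlinear optimisation did not converge."""


class MissingReferenceError(IsodilError, ValueError):
    """A required reference treatment (NoP / MinP) is absent."""


class SchemaError(IsodilError, ValueError):
    """An input table violates its schema.

    Attributes
    ----------
    violations : list of str
        Human-readable description of each violation, with row numbers
        where applicable.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class DependencyError(IsodilError, ValueError):
    """A pipeline stage was requested without its required inputs."""
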