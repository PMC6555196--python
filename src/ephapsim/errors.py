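"""Exception hierarchy shared across the package."""


class EphapsimError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EphapsimError):
    """A domain object or argument violates its invariants."""


class NamingError(ValidationError):
    """Duplicate or unresolved identifier."""


class FormatError(EphapsimError):
    """Malformed external file (SWC, config, result schema)."""


class SingularityError(EphapsimError):
    """Field evaluation requested on the singular axis of a source."""


class ConditioningError(EphapsimError):
    """The closed-loop linear system is singular or near-singular."""


class SolverError(EphapsimError):
    """Integrator failure (non-convergence, step-size collapse)."""


class StimulusError(EphapsimError):
    """A user-supplied stimulus function raised; context attached."""
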