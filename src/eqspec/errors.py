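"""Exception hierarchy for eqspec."""


class EqspecError(Exception):
    """Base class for all eqspec errors."""


class ModelError(EqspecError):
    """Invalid or incomplete equilibrium model definition."""


class SchemaError(ModelError):
    """Malformed species/component table."""


class SolverError(EqspecError):
    """Newton-Raphson speciation failure.

    Carries the last iterate in ``state`` so callers can inspect how far
    the solver got.
    """

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


class FitError(EqspecError):
    """Newton-Gauss fit driver failure."""


class IdentifiabilityError(FitError):
    """Singular normal equations; parameters jointly unidentifiable.

    ``correlated`` names the offending parameter group when known.
    """

    def __init__(self, message, correlated=None):
        super().__init__(message)
        self.correlated = correlated or []


class WorkflowError(EqspecError):
    """Recovery-cascade bookkeeping error (missing prerequisite stage etc.)."""
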