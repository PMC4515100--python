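"""Exception hierarchy for mipred."""


class MipredError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MipredError, ValueError):
    """An argument violates a documented precondition."""


class MissingTermError(MipredError, KeyError):
    """A model term cannot be resolved from the dataset columns."""


class StageFitError(MipredError):
    """A missingness-stage logistic model failed to converge."""


class ImputationError(MipredError):
    """Chained-equations imputation could not proceed (e.g. no donors)."""


class FitError(MipredError):
    """A prediction-model fit failed (separation, non-convergence, rank)."""


class ProvenanceError(MipredError):
    """An imputed stack was used in a role its construction forbids."""


class RoutingError(MipredError):
    """No partial prediction model exists for an observed-covariate pattern."""


class DegenerateOutcomeError(MipredError):
    """A measure needs both outcome classes but only one is present."""


class UndefinedSlopeError(MipredError):
    """Calibration slope is undefined for constant predictions."""


class ScenarioError(MipredError):
    """A simulation scenario exceeded its replicate failure budget."""
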