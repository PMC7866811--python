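"""Exception hierarchy for the neurotme pipeline.

Every stage raises a subclass of :class:`NeurotmeError`, so callers (and the
pipeline driver, which records per-stage failures instead of crashing) can
catch one base type.
"""


class NeurotmeError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(NeurotmeError):
    """Polygon is degenerate (fewer than 3 vertices, self-intersecting, ...)."""


class FormatError(NeurotmeError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(NeurotmeError):
    """A record violates a domain-type invariant."""


class MissingAnnotationError(NeurotmeError):
    """A required region annotation (roi, total_tissue, tumor glands) is absent."""


class InvalidAnnotationError(NeurotmeError):
    """Region annotations are mutually inconsistent (e.g. negative stroma area)."""


class UndefinedCellularityError(NeurotmeError):
    """Tumor cellularity is undefined because tumor + stroma area is zero."""


class ConfigurationError(NeurotmeError):
    """A configuration value is out of range or infeasible."""


class DegenerateInputError(NeurotmeError):
    """Input data carry too little information for the requested estimate."""


class TrainingError(NeurotmeError):
    """Classifier training set is unusable (e.g. a class is absent)."""


class EvaluationError(NeurotmeError):
    """Prediction/truth tables cannot be matched for evaluation."""


class DegenerateDesignError(NeurotmeError):
    """Regression design matrix is rank-deficient or has a constant column."""


class ConvergenceError(NeurotmeError):
    """Iterative fit failed to converge; message carries diagnostics."""


class HierarchyError(NeurotmeError):
    """An interaction term is present without both of its main effects."""


class JoinError(NeurotmeError):
    """Slide-level and patient-level tables cannot be joined."""


class DomainError(NeurotmeError):
    """A scalar argument is outside its mathematical domain."""
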