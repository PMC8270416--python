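"""Exception types shared across the package."""


class TractSGLError(Exception):
    """Base class for package errors."""


class FormatError(TractSGLError):
    """A CSV file does not conform to the expected dialect."""


class IntegrityError(TractSGLError):
    """Input data violates a uniqueness or cross-file consistency rule."""


class StructuralError(TractSGLError):
    """The profile table cannot be assembled into a grouped feature matrix."""


class DimensionError(TractSGLError, ValueError):
    """Array shapes are inconsistent."""


class ImputationError(TractSGLError):
    """A subject x group profile cannot be imputed."""


class PolicyError(TractSGLError):
    """An imputation policy precondition is violated."""


class DomainError(TractSGLError, ValueError):
    """Target values are outside the domain of the requested transform."""


class StratificationError(TractSGLError):
    """Stratified folds cannot be built from the given labels."""


class SpecError(TractSGLError, ValueError):
    """A synthetic-data specification is infeasible."""


class ConfigError(TractSGLError, ValueError):
    """A run configuration is invalid."""
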