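"""Exception hierarchy for jointlogit.

Exit-code mapping used by the CLI: config problems -> 2, data problems -> 3,
estimation/convergence problems -> 4.
"""


class JointlogitError(Exception):
    """Base class for all package errors."""


class ConfigError(JointlogitError):
    """Invalid run/simulation configuration."""


class ParameterizationError(ConfigError):
    """Covariance or coefficient specification is invalid (e.g. non-PSD)."""


class DimensionError(ConfigError):
    """Zero-size hierarchy or mismatched dimensions."""


class DataError(JointlogitError):
    """Base class for dataset problems."""


class SchemaError(DataError):
    """Column-role schema does not match the file."""


class NestingError(DataError):
    """A household appears under more than one cluster."""


class DomainError(DataError):
    """Outcome value outside {0, 1, missing}."""


class EmptyTableError(DataError):
    """No complete-outcome records to tabulate."""


class EstimationError(JointlogitError):
    """Base class for model-fitting problems."""


class SeparationError(EstimationError):
    """An outcome is constant (or perfectly separated) in the analysis set."""


class ComparabilityError(EstimationError):
    """Two fits being compared were not produced on the same data/settings."""


class PipelineError(JointlogitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
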