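"""Exception hierarchy. Every error raised on purpose derives from GbmrsError."""


class GbmrsError(Exception):
    """Base class for package errors."""


class ConfigurationError(GbmrsError):
    """Invalid simulation or pipeline configuration."""


class SimulationError(GbmrsError):
    """A simulation step could not honour its contract."""


class PreprocessingError(GbmrsError):
    """Phenotype preprocessing failure (e.g. zero within-sex variance)."""


class QCError(GbmrsError):
    """Genotype quality control removed everything or was misconfigured."""


class UsageError(GbmrsError):
    """An operation was called with inconsistent arguments."""


class ConvergenceError(GbmrsError):
    """The coordinate-descent solver failed to converge."""


class SelectionError(GbmrsError):
    """Regularization-strength selection failed (e.g. constant validation y)."""


class EnsembleError(GbmrsError):
    """A cross-validation fold failed during ensemble training."""


class ApplicationError(GbmrsError):
    """A predictor could not be applied to a feature matrix."""


class EvaluationError(GbmrsError):
    """An evaluation metric is undefined for the given inputs."""


class ParseError(GbmrsError):
    """A delimited input file is malformed."""
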