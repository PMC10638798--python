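"""Exception hierarchy used across the package."""


class BcsCeaError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BcsCeaError):
    """A config file is missing, unparsable, or lacks a required field."""


class ValidationError(BcsCeaError):
    """A parameter value violates its documented invariant."""


class ParameterError(BcsCeaError):
    """An operation was called with an out-of-domain argument."""


class InfeasibleParametersError(BcsCeaError):
    """A transition-matrix row complement went negative for the given inputs."""


class EstimationError(BcsCeaError):
    """A registry-based estimate cannot be formed (e.g. an empty arm)."""


class AnalysisError(BcsCeaError):
    """An incremental analysis was requested on unusable inputs."""
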