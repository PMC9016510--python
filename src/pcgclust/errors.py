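"""Package-wide exception types."""


class PCGClustError(Exception):
    """Base class for all pcgclust errors."""


class ValidationError(PCGClustError, ValueError):
    """Invalid data passed to a pipeline operation."""


class ConfigurationError(PCGClustError, ValueError):
    """Invalid or incomplete configuration (taxonomy, specs, hyperparameters)."""


class StateError(PCGClustError, RuntimeError):
    """Operation invoked on an object in the wrong state (e.g. unfitted forest)."""
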