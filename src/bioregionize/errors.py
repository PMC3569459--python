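"""Exception hierarchy shared across the pipeline stages."""


class BioregionizeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BioregionizeError, ValueError):
    """Invalid configuration object or missing input file."""


class InputError(BioregionizeError, ValueError):
    """Malformed or inconsistent user input (unknown ids, dimension mismatch)."""


class DataError(BioregionizeError, ValueError):
    """Data fails a statistical precondition (all-missing, zero variance, ...)."""


class EvaluationError(BioregionizeError, RuntimeError):
    """A model evaluation could not be carried out (e.g. too few presences)."""


class StateError(BioregionizeError, RuntimeError):
    """An object was used before reaching the required state."""
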