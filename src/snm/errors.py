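"""Exception hierarchy for the snm package."""


class SNMError(Exception):
    """Base class for all snm-specific errors."""


class DynamicsError(SNMError):
    """Numerical blow-up (non-finite state or input) during neuron integration."""


class ConfigurationError(SNMError, ValueError):
    """Invalid network or experiment configuration."""


class DataError(SNMError, ValueError):
    """Invalid dataset content (labels out of range, negative features, ...)."""


class StateError(SNMError, RuntimeError):
    """Operation applied to a model in the wrong state (e.g. unlearning an untrained model)."""


class FormatError(SNMError):
    """Model container version mismatch or corruption."""
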