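"""Exception types shared across the package."""


class MetaNeuronError(Exception):
    """Base class for all package errors."""


class InvalidStateError(MetaNeuronError):
    """A neuron state contains non-finite or otherwise unusable components."""


class IntegrationError(MetaNeuronError):
    """Numerical integration failed (e.g. blow-up from an oversized time step)."""


class ConfigError(MetaNeuronError):
    """A configuration file or parameter set violates its contract."""
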