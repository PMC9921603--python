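"""Exception hierarchy shared across the package."""


class ElbowStiffError(Exception):
    """Base class for all package errors."""


class ParameterError(ElbowStiffError, ValueError):
    """A model or configuration parameter is out of its admissible domain."""


class DataError(ElbowStiffError, ValueError):
    """Input series are malformed (NaN, length mismatch, non-monotone time...)."""


class SchemaError(DataError):
    """A file does not match the expected column/key schema."""


class InvalidSamplingRateError(ParameterError):
    """Sampling rate too low for the requested filtering."""


class StateError(ElbowStiffError, RuntimeError):
    """The simulation reached a physically inconsistent state (e.g. lt < 0)."""


class DivergenceError(StateError):
    """The forward simulation left the configured angle guard band."""
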