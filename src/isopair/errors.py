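"""Exception hierarchy shared across the pipeline stages."""


class IsopairError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IsopairError, ValueError):
    """Invalid simulation or run configuration (unknown keys, bad values)."""


class InputFormatError(IsopairError, ValueError):
    """Malformed input data (bad intervals, missing columns, unknown labels)."""


class ComputationError(IsopairError, RuntimeError):
    """A stage could not produce a result from otherwise valid inputs."""
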