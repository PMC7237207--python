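"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class ConfigError(ValueError):
    """A configuration file or mapping is malformed or inconsistent."""


class DataError(ValueError):
    """Input data are missing, malformed, or insufficient for an analysis."""
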