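class ConfigurationError(ValueError):
    """Invalid run configuration (CLI exit code 1)."""


class DataError(RuntimeError):
    """Missing or malformed data (CLI exit code 2)."""


class NoROIError(DataError):
    """Foreground extraction found no region of interest."""
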