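"""Exception types shared across the pipeline."""


class BloodsiftError(Exception):
    """Base class for all package errors."""


class ConfigError(BloodsiftError):
    """Invalid configuration (unknown key, bad type, out-of-range value)."""


class DataError(BloodsiftError):
    """Input data violates a precondition (malformed file, empty matrix...)."""
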