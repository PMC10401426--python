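"""Shared exception types."""


class ConfigError(ValueError):
    """An invalid configuration (non-positive rate, unknown unit, ...)."""


class ValidationError(ValueError):
    """Input data violating a documented contract."""
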