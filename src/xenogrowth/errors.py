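"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Raised when input data violate a documented precondition."""


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails schema validation."""
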