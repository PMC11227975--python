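"""Exception types shared across the package."""


class InputError(ValueError):
    """Raised when user-supplied data violate a documented precondition."""


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent."""


class PipelineError(RuntimeError):
    """Raised when one or more pipeline stages fail; the manifest records partial completion."""
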