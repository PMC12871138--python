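"""Exception hierarchy shared across the package.

The CLI maps :class:`ConfigError` to exit code 2 and
:class:`ValidationError` to exit code 3.
"""


class SecretomapError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SecretomapError):
    """Invalid run configuration: bad parameter, missing path, unknown contrast."""


class ValidationError(SecretomapError):
    """Data violates a documented invariant (duplicate IDs, negative intensity, ...)."""


class SchemaError(ValidationError):
    """A table is missing a required column or a column has no design row."""


class StageError(SecretomapError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str, path: str | None = None):
        self.stage = stage
        self.path = path
        loc = f" (input: {path})" if path else ""
        super().__init__(f"stage '{stage}' failed{loc}: {message}")
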