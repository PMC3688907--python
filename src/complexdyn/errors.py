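"""Exception types shared across the package."""


class ComplexdynError(Exception):
    """Base class for package errors."""


class FormatError(ComplexdynError, ValueError):
    """An input file violates its declared format."""


class ConfigError(ComplexdynError, ValueError):
    """A parameter or configuration value is out of its valid range."""


class PipelineError(ComplexdynError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
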