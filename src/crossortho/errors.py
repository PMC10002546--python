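"""Exception types shared across the pipeline."""


class PipelineError(Exception):
    """Base class for crossortho errors."""


class FormatError(PipelineError):
    """A file's content violates its declared format."""


class ConfigError(PipelineError):
    """A configuration value is invalid or infeasible."""


class EmptyAfterQCError(PipelineError):
    """Quality-control filtering removed every cell."""
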