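"""Exception hierarchy shared by all pipeline stages."""


class MeripArrayError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(MeripArrayError, ValueError):
    """A configuration value or parameter is invalid; the message names the field."""


class DataError(MeripArrayError, ValueError):
    """Input data violate a precondition (format, missing columns, degenerate values)."""


class PipelineError(MeripArrayError, RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""
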