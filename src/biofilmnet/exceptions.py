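"""Exception hierarchy shared across the package."""


class BiofilmnetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BiofilmnetError, ValueError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(BiofilmnetError, ValueError):
    """An in-memory object violates one of its invariants."""


class ConfigError(BiofilmnetError, ValueError):
    """A configuration value is out of range or inconsistent."""


class PipelineError(BiofilmnetError, RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""
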