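"""Exception hierarchy shared across the pipeline."""


class StramTFError(Exception):
    """Base class for all package errors."""


class ParseError(StramTFError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(StramTFError):
    """A tabular input is missing required columns or has bad values."""


class ConfigurationError(StramTFError):
    """Required configuration (e.g. a gathering cutoff) is missing."""


class ConsistencyError(StramTFError):
    """Cross-input label sets (species, families) disagree."""
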