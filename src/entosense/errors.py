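"""Exception types shared across the pipeline."""


class EntosenseError(Exception):
    """Base class for all package errors."""


class ConfigError(EntosenseError):
    """A configuration value is missing, out of range, or inconsistent."""


class DataError(EntosenseError):
    """Input data violate a precondition (lengths, schema, ordering ...)."""


class RecordingFormatError(DataError):
    """A recording file does not match the expected on-disk schema."""
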