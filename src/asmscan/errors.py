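"""Exception hierarchy for the asmscan pipeline."""


class AsmscanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AsmscanError):
    """An invalid configuration value; the message names the field."""


class DataError(AsmscanError):
    """Malformed or inconsistent input data."""


class SchemaError(DataError):
    """A table does not match its declared schema; names the column."""
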