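"""Exception types shared across the package."""


class CrctnmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CrctnmError):
    """A configuration file, lexicon, or column mapping is invalid."""


class ValidationError(CrctnmError):
    """Input data violates a contract (duplicate ids, schema mismatch, ...)."""
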