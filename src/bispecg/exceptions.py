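"""Exception hierarchy for bispecg."""


class BispecgError(Exception):
    """Base class for all bispecg errors."""


class FormatError(BispecgError, ValueError):
    """A file could not be parsed as the expected format."""


class ConfigurationError(BispecgError, ValueError):
    """Required configuration (e.g. a sampling frequency) is missing or invalid."""


class ParameterError(BispecgError, ValueError):
    """A numeric parameter violates its precondition."""


class DataError(BispecgError, ValueError):
    """Input data violates a precondition (too short, non-finite, wrong shape)."""


class SplitError(DataError):
    """A train/test split cannot be formed (e.g. a class with one record)."""
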