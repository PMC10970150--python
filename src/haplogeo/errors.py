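"""Exception hierarchy for haplogeo."""


class HaplogeoError(Exception):
    """Base class for all haplogeo errors."""


class FormatError(HaplogeoError, ValueError):
    """A file could not be parsed as the expected format."""


class AlignmentLengthError(FormatError):
    """Records of a putative alignment have unequal lengths."""


class ValidationError(HaplogeoError, ValueError):
    """Input data violate a structural invariant (duplicates, bad codes...)."""


class SchemaError(ValidationError):
    """A table is missing required columns."""


class DegenerateDataError(HaplogeoError, ValueError):
    """An operation removed or received no usable data (e.g. all sites masked)."""


class InsufficientDataError(HaplogeoError, ValueError):
    """Too few samples / pairs for the requested statistic."""
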