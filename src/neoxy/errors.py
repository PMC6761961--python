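"""Exception types shared across the package."""


class NeoxyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeoxyError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class AlignmentInputError(NeoxyError, ValueError):
    """Sequences handed to an alignment-consuming routine are unusable."""


class SaturationError(NeoxyError, ArithmeticError):
    """Synonymous divergence too high for the distance correction (pS >= 3/4)."""


class InternalStopError(NeoxyError, ValueError):
    """A coding sequence contains an in-frame stop codon."""


class LengthMismatchError(NeoxyError, ValueError):
    """Aligned coding sequences differ in length or are not codon-sized."""
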