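"""Exception hierarchy.

The CLI maps :class:`ValidationError` (bad inputs, broken chip definitions,
malformed files) to exit status 2 and everything else to exit status 1.
"""


class GcscoreError(Exception):
    """Base class for all package errors."""


class ValidationError(GcscoreError):
    """Input data violates a structural invariant (bad chip bundle, bad table)."""


class UnsupportedFormatError(ValidationError):
    """File is in a recognised but unsupported format (e.g. binary Calvin CEL)."""


class DegenerateInputError(GcscoreError):
    """Numerically degenerate input (zero median, too few probes, zero epsilon)."""


class DegenerateDistributionError(DegenerateInputError):
    """Raw score distribution has zero spread; normalization is undefined."""
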