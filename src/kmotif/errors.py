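"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation/format/design problems exit
with 1, usage errors with 2.
"""


class KmotifError(Exception):
    """Base class for all package errors."""


class FormatError(KmotifError):
    """An input file is not in the expected format (e.g. GenBank without a
    sequence block)."""


class ValidationError(KmotifError):
    """Inputs are well-formed but inconsistent (coordinates out of bounds,
    reference-base mismatch, missing metadata rows, ...)."""


class DesignError(KmotifError):
    """A substrate design is geometrically impossible with the requested
    lengths (deletion at a genome edge, primer too short to bridge a round)."""


class UsageError(KmotifError):
    """The caller asked for something nonsensical (unknown output format,
    inverted spacer bounds, mixed repeat lengths)."""
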