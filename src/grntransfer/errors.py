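"""Exception hierarchy shared across the package."""


class GrnTransferError(Exception):
    """Base class for all package errors."""


class FormatError(GrnTransferError):
    """An on-disk artifact does not match its declared dialect."""


class EmptyAnnotationError(FormatError):
    """An annotation source contained no CDS features."""


class UnknownGeneError(GrnTransferError, KeyError):
    """A gene identifier does not belong to the declared genome/network."""


class UsageError(GrnTransferError, ValueError):
    """A parameter or argument is outside its legal domain."""


class InvariantError(GrnTransferError):
    """An internal data-structure invariant was breached."""
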