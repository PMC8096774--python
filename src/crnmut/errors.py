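"""Exception hierarchy shared across the package."""


class CRNError(Exception):
    """Base class for all crnmut errors."""


class ParseError(CRNError):
    """A network table could not be parsed; the message names the row."""


class ValidationError(CRNError):
    """A parsed network violates a structural invariant."""


class ContractError(CRNError):
    """An operation was called with inconsistent dimensions or arguments."""


class UnsupportedStructureError(CRNError):
    """The conservation structure does not support the requested operation
    (e.g. the network is not weakly elemented, or the generator set exceeds
    the left-null-space dimension)."""


class IntegrityError(CRNError):
    """A numerical result violates a physical invariant (conservation drift,
    concentrations below the negativity tolerance)."""
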