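"""Exception hierarchy shared across the package."""


class GremlkitError(Exception):
    """Base class for all gremlkit errors."""


class ParseError(GremlkitError):
    """A text input file could not be parsed; the message names the line."""


class FormatError(GremlkitError):
    """A binary or structured file violates its declared layout."""


class ValidationError(GremlkitError):
    """Inputs violate a documented precondition or invariant."""


class DegenerateDataError(GremlkitError):
    """Data are structurally unable to support the requested computation
    (e.g. no polymorphic SNPs, a pair with no shared genotyped SNPs)."""


class NonIdentifiableError(GremlkitError):
    """The variance-component model is not identifiable from the supplied
    relationship matrix (singular average-information matrix)."""
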