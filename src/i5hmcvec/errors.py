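"""Exception hierarchy.

Every error raised by this package derives from :class:`I5hmCVecError`, so
callers can catch one base class.  Subclasses also derive from the matching
builtin (``KeyError``/``ValueError``) to behave well in generic code.
"""


class I5hmCVecError(Exception):
    """Base class for all package errors."""


class InvalidInputError(I5hmCVecError, ValueError):
    """An argument violates a documented precondition."""


class MissingReferenceError(I5hmCVecError, KeyError):
    """A chromosome or other named reference is absent from the input."""


class CoordinateError(I5hmCVecError, ValueError):
    """An interval lies outside its chromosome bounds."""


class EmptyVocabularyError(I5hmCVecError, ValueError):
    """A corpus yielded no valid k-mer to train on."""


class FormatError(I5hmCVecError, ValueError):
    """A file does not conform to the expected text format."""


class TooShortError(InvalidInputError):
    """A sequence is shorter than the requested k."""


class UnencodableSequenceError(I5hmCVecError, ValueError):
    """No k-mer of a sequence could be looked up in the vocabulary."""


class DegenerateLabelsError(InvalidInputError):
    """A classifier was given samples from a single class."""


class DegenerateInputError(InvalidInputError):
    """An operation received degenerate data (e.g. all points identical)."""
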