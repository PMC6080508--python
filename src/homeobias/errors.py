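"""Exception hierarchy shared by all modules."""


class HomeobiasError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(HomeobiasError, ValueError):
    """A file or table does not conform to the expected dialect."""


class InvalidInputError(HomeobiasError, ValueError):
    """An in-memory argument violates a precondition."""


class InvalidParameterError(InvalidInputError):
    """A configuration parameter is outside its allowed range."""


class LookupMismatchError(HomeobiasError, KeyError):
    """Identifiers expected in a table are absent."""
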