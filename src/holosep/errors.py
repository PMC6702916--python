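"""Exception types shared across the package."""


class HolosepError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HolosepError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyIndexError(HolosepError):
    """A rank index was requested from an empty k-mer table."""


class DegenerateClusteringError(HolosepError):
    """All posterior values are identical; two clusters cannot be formed."""


class PairedFileError(HolosepError):
    """Mate files disagree in record count or read identifiers."""


class InputMismatchError(HolosepError):
    """Predicted and truth label sets cover different fragment ids."""
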