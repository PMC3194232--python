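"""Exception types shared across the package."""


class DmoiobError(Exception):
    """Base class for all package errors."""


class MatrixParseError(DmoiobError, ValueError):
    """A matrix file could not be parsed (ragged rows, non-numeric cells)."""


class EncodingError(DmoiobError, ValueError):
    """A bicluster bit-string has the wrong length or illegal characters."""


class DomainError(DmoiobError, ValueError):
    """An operation was applied to a degenerate input (e.g. empty bicluster)."""


class ParameterError(DmoiobError, ValueError):
    """A numeric parameter is outside its legal range."""


class GuideError(DmoiobError, RuntimeError):
    """Leader selection was attempted against an empty archive."""
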