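"""Typed exceptions raised across the package.

All readers and pipeline stages raise one of these instead of bare
``ValueError`` so callers (and the CLI) can distinguish malformed input
from invalid parameters.
"""


class ImmunosigError(Exception):
    """Base class for package errors."""


class DataFormatError(ImmunosigError):
    """A file could not be parsed (ragged rows, bad header, out-of-bounds
    sparse index, unknown schema version, ...)."""


class ValidationError(ImmunosigError):
    """Well-formed input violating a contract (duplicate identifiers,
    negative counts, GC fraction outside [0, 1], dimension mismatch, ...)."""


class ConvergenceWarning(UserWarning):
    """Solver stopped at ``max_iter`` before reaching its tolerance."""
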