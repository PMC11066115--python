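"""Error types shared across the package."""


class CamAngioError(Exception):
    """Base class for all package errors."""


class ValidationError(CamAngioError, ValueError):
    """Raised when inputs violate a documented precondition or invariant."""


class CineIOError(CamAngioError, IOError):
    """Raised when a cine/image/annotation file cannot be read or written."""
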