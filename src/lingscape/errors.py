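"""Exception types shared across the package."""


class LingscapeError(Exception):
    """Base class for package errors."""


class ValidationError(LingscapeError):
    """A record or table violates one of its documented invariants."""


class GeometryError(LingscapeError):
    """Invalid or degenerate geometry input."""
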