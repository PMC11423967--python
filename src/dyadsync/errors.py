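"""Exception hierarchy."""


class DyadsyncError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DyadsyncError, ValueError):
    """A structured input file violated its format contract."""


class ValidationError(DyadsyncError, ValueError):
    """Data violated a documented invariant."""


class SessionError(DyadsyncError, RuntimeError):
    """A dyadic session could not be assembled (e.g. empty overlap)."""
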