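"""Exception types shared across the package."""


class RingAnchorError(Exception):
    """Base class for all package errors."""


class FormatError(RingAnchorError, ValueError):
    """A file does not conform to its expected dialect."""


class CoverageError(RingAnchorError, ValueError):
    """A requested calendar year lies outside a curve or reference span."""

    def __init__(self, message: str, missing_years=()):
        super().__init__(message)
        self.missing_years = tuple(missing_years)


class PairingError(RingAnchorError, ValueError):
    """Replicate measurements cannot be paired as requested."""
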