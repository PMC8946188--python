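"""Exception hierarchy shared across the package."""


class RanovolError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RanovolError, ValueError):
    """A table or file is structurally malformed (e.g. a required column is missing)."""


class ValidationError(RanovolError, ValueError):
    """Input values violate a domain invariant (e.g. non-positive volume)."""
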