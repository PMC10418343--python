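"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 2, ``NumericalError`` to 3.
"""


class IrcmechError(Exception):
    """Base class for all package errors."""


class ValidationError(IrcmechError):
    """Input violates a structural or domain invariant."""


class FormatError(IrcmechError):
    """External file cannot be parsed into the expected representation."""


class NumericalError(IrcmechError):
    """A numerical procedure failed (singular fit, no barrier, ...)."""
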