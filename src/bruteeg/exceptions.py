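"""Exception hierarchy shared across the package."""


class BruteEEGError(Exception):
    """Base class for all package errors."""


class ValidationError(BruteEEGError, ValueError):
    """An input violates a documented invariant; the message names the field."""


class FormatError(BruteEEGError, ValueError):
    """A container file does not follow the documented layout."""


class StateError(BruteEEGError, RuntimeError):
    """An operation was called before its required fitting step."""
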