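"""Exception hierarchy shared across the package."""


class TexsepError(Exception):
    """Base class for all texsep errors."""


class ConfigurationError(TexsepError):
    """A configuration value is invalid (unknown kind, out-of-range count, ...)."""


class InputError(TexsepError):
    """An input object violates a precondition (bad shape, empty folder, ...)."""
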