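"""Exception types shared across the package."""


class MirtrendError(Exception):
    """Base class for all package-specific failures."""


class ValidationError(MirtrendError, ValueError):
    """An input object violated its contract (bad interval, bad spec, ...)."""
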