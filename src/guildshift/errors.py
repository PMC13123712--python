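"""Exception hierarchy shared across the pipeline."""


class GuildshiftError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(GuildshiftError):
    """A file could not be parsed into a valid table."""


class ValidationError(GuildshiftError):
    """An in-memory table violates one of its invariants."""
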