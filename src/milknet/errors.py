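"""Exception types shared across the package."""


class MilknetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MilknetError, ValueError):
    """Invalid simulation or pipeline configuration."""


class FormatError(MilknetError, ValueError):
    """Malformed input file (bad magic bytes, truncated records, ...)."""


class MonomorphicSNPError(MilknetError, ValueError):
    """An operation that requires polymorphic markers saw a fixed one."""


class EmptyResultError(MilknetError, RuntimeError):
    """A filtering step removed everything; raised instead of silently
    returning an empty object."""
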