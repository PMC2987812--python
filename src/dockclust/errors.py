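"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`DockclustError` so the CLI can map
failures onto stable exit codes (input/format problems vs. internal errors).
"""


class DockclustError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(DockclustError):
    """A docking table does not conform to the declared dialect."""


class ParseError(DockclustError):
    """A cell in a docking table could not be interpreted as a number."""


class InputError(DockclustError):
    """Structurally valid input that violates an operation's precondition."""


class ConfigError(DockclustError):
    """An invalid configuration value (unknown dialect, convention, ...)."""
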