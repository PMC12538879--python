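"""Exception hierarchy shared by all atacmux modules.

Every error raised on bad user input derives from :class:`AtacmuxError`, so
the command-line layer can catch one type and exit with a one-line
diagnostic.
"""


class AtacmuxError(Exception):
    """Base class for all toolkit errors."""


class InputError(AtacmuxError):
    """A required input file is missing or unreadable."""


class ParseError(AtacmuxError):
    """A line of an input file violates the format contract."""


class ConfigError(AtacmuxError):
    """A parameter combination is invalid (e.g. fewer than two samples)."""


class ConsistencyError(AtacmuxError):
    """Two inputs that must describe the same universe disagree."""


class UndefinedMetricError(AtacmuxError):
    """A metric was requested on input where it has no defined value."""
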