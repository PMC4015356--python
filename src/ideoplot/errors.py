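"""Exception hierarchy.

The CLI maps these onto exit codes: data problems (bad input files,
out-of-range coordinates) exit 1, usage problems (bad flags, malformed
zoom strings) exit 2.
"""


class IdeoplotError(Exception):
    """Base class for all errors raised by this package."""


class InputFormatError(IdeoplotError):
    """A data file (annotation TSV or cytoBand file) is malformed.

    Carries ``line_no`` when the problem is attributable to one line.
    """

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class UsageError(IdeoplotError):
    """The caller asked for something the interface does not offer."""


class ConfigurationError(IdeoplotError):
    """The installation itself is broken (e.g. missing bundled data)."""
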