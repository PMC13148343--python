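"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes so shell pipelines can
distinguish a bad configuration from malformed input or degenerate data.
"""


class EploopsError(Exception):
    """Base class for all package errors."""


class ConfigError(EploopsError):
    """A configuration value is missing, unknown, or out of its domain."""

    exit_code = 2


class InputFormatError(EploopsError):
    """An input file violates its format contract."""

    exit_code = 3


class DegenerateDataError(EploopsError):
    """The data is structurally valid but too degenerate to analyse."""

    exit_code = 4
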