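"""Exception hierarchy; exit codes used by the command-line layer."""


class TiraError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(TiraError):
    """Invalid configuration or parameters."""

    exit_code = 2


class DataError(TiraError):
    """Malformed or inconsistent input data."""

    exit_code = 3


class StageError(TiraError):
    """A pipeline stage failed; partial outputs are preserved."""

    exit_code = 4
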