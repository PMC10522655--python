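"""Exception hierarchy; the CLI maps these onto exit codes."""


class ItrapError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class ConfigError(ItrapError):
    """Invalid configuration or usage (exit code 2)."""

    exit_code = 2


class DataFormatError(ItrapError):
    """Malformed input file: missing columns, unparseable values (exit code 3)."""

    exit_code = 3


class IntegrityError(ItrapError):
    """Internal consistency violation, e.g. duplicate barcodes (exit code 4)."""

    exit_code = 4
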