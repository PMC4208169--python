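"""Exception hierarchy shared across the package.

``HarfError`` subclasses carry the process exit status used by the
command-line interface, so configuration, file-format and model/feature
compatibility failures exit with distinct nonzero codes.
"""


class HarfError(Exception):
    """Base class for recoverable errors raised by this package."""

    exit_code = 1


class ConfigError(HarfError):
    """Invalid run configuration, registry contents, or missing models."""

    exit_code = 3


class FormatError(HarfError):
    """Malformed input file (sensor-log CSV, model or registry JSON)."""

    exit_code = 4


class OrderingError(FormatError):
    """Timestamps within a single sensor stream decrease."""


class SchemaVersionError(FormatError):
    """Model or registry schema version missing or unsupported."""


class CompatibilityError(HarfError):
    """Feature name/order mismatch between a vector and a model set."""

    exit_code = 5
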