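"""Exception hierarchy.

Two top-level families matter to the command line: configuration problems
(exit code 2) and input-data problems (exit code 3). Everything raised by
the library derives from :class:`DoseTraceError`.
"""


class DoseTraceError(Exception):
    """Base class for all errors raised by dosetrace."""

    exit_code = 1


class ConfigError(DoseTraceError):
    """Invalid run configuration (bad parameter value, malformed config file)."""

    exit_code = 2


class InputError(DoseTraceError):
    """Invalid input data."""

    exit_code = 3


class SchemaError(InputError):
    """A required column or field is missing from an input table."""


class DesignError(InputError):
    """Input table is inconsistent with the dose design (e.g. channel count)."""


class ValidationError(InputError):
    """A row failed validation against its declared type."""


class DegenerateTraceError(InputError):
    """A dose trace has too few points to analyse (fewer than 3)."""


class PairingError(InputError):
    """Replicate curves could not be paired (entity mismatch, unequal grids)."""
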