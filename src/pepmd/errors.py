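"""Exception hierarchy.

All package errors derive from :class:`PepmdError` so callers (and the CLI)
can distinguish configuration problems from data problems.
"""


class PepmdError(Exception):
    """Base class for all pepmd errors."""


class ConfigError(PepmdError):
    """Invalid configuration or specification parameters (CLI exit code 2)."""


class DataError(PepmdError):
    """Invalid or insufficient input data (CLI exit code 3)."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line."""


class StructureError(DataError):
    """Structurally inconsistent molecular input (e.g. atom count mismatch)."""


class SelectionError(DataError):
    """An atom selection resolved to no atoms."""


class GeometryError(DataError):
    """Degenerate geometry (collinear fit atoms, zero-length vectors)."""


class ScheduleError(DataError):
    """A lambda-window schedule does not tile [0, 1]."""


class ContractError(PepmdError):
    """An internal API contract was violated (missing provenance, mismatched
    temperatures, ...)."""
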