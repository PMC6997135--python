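"""Exception hierarchy for compmd.

Every error raised on purpose by the package derives from :class:`CompmdError`
so callers can distinguish validation failures from genuine bugs.
"""


class CompmdError(Exception):
    """Base class for all compmd errors."""


class EmptyStructureError(CompmdError):
    """PDB content contained no ATOM/HETATM records."""


class ModelMismatchError(CompmdError):
    """Models of a multi-model PDB disagree on atom count/identity."""


class FormatOverflowError(CompmdError):
    """A value cannot be represented in fixed-column PDB format."""


class SchemaError(CompmdError):
    """A delimited table is missing required columns."""


class TableParseError(CompmdError):
    """A delimited table contains an unparseable or invalid cell."""


class DuplicateKeyError(CompmdError):
    """A table key that must be unique appeared more than once."""


class SelectionError(CompmdError):
    """Malformed atom-selection expression (carries the offending position)."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class DegenerateGeometryError(CompmdError):
    """Selection too small or collinear for superposition."""


class InsufficientFramesError(CompmdError):
    """Operation requires more frames than the trajectory provides."""


class MissingParameterError(CompmdError):
    """An atom lacks the per-atom parameters required by an energy term."""


class ClashError(CompmdError):
    """Two interacting atoms are unphysically close."""


class NoHydrogensError(CompmdError):
    """Hydrogen-bond detection requires explicit hydrogens."""


class ConfigError(CompmdError):
    """Pipeline configuration failed validation."""
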