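"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`EnsembleBindError`, so callers can catch one type at pipeline level.
"""


class EnsembleBindError(Exception):
    """Base class for all errors raised by ensemblebind."""


class PDBParseError(EnsembleBindError):
    """A PDB record could not be parsed; the message names the line."""


class TopologyError(EnsembleBindError):
    """Frames or poses disagree on atom count/order; names the offending frame."""


class FormatError(EnsembleBindError):
    """A CSV or config file violates its documented dialect."""


class GeometryError(EnsembleBindError):
    """Degenerate geometry (too few atoms, collinear selection, empty grid)."""


class FitError(EnsembleBindError):
    """Nonlinear fit failed to converge; message carries diagnostics."""


class AnalysisError(EnsembleBindError):
    """Invalid input to an analysis operation (empty selection, single frame...)."""
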