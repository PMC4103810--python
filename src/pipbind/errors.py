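"""Exception hierarchy for pipbind."""


class PipbindError(Exception):
    """Base class for all package-specific errors."""


class DegenerateCalibrationError(PipbindError):
    """Anisotropy calibration with r_bound == r_free cannot convert signals."""


class UndefinedSeparationError(PipbindError):
    """Z' is undefined when positive and negative control means coincide."""


class InsufficientReplicatesError(PipbindError):
    """Too few replicate measurements for the requested statistic."""


class NumericalFailureError(PipbindError):
    """An equilibrium solver or optimizer failed to reach its tolerance."""


class SeriesValidationError(PipbindError):
    """A titration/competition series violates its structural invariants."""


class ParseError(PipbindError):
    """Malformed input file (CSV/FASTA/PDB)."""


class SelectionError(PipbindError):
    """An atom/residue selection matched nothing or was malformed."""
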