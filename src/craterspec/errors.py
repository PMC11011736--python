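"""Exception hierarchy for craterspec.

All data / numerical failures raise a :class:`CraterSpecError` subclass so the
CLI can map them to a single non-zero exit code with a one-line diagnosis.
"""


class CraterSpecError(Exception):
    """Base class for all craterspec errors."""


class DataFormatError(CraterSpecError, ValueError):
    """A file or table violates the expected layout (ragged axes, duplicates, non-numeric cells)."""


class AlignmentError(CraterSpecError, ValueError):
    """Sample identifiers of paired containers do not match."""


class NormalizationError(CraterSpecError, ValueError):
    """A spectrum cannot be normalized (non-positive total area)."""


class CorrectionError(CraterSpecError, ValueError):
    """Spectral correction failed (e.g. non-positive matrix-variable mean)."""


class SelectionError(CraterSpecError, ValueError):
    """Variable selection cannot proceed (no valid candidates, degenerate references)."""


class ModelError(CraterSpecError, ValueError):
    """A regression model cannot be fitted or applied (rank deficiency, bad configuration)."""
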