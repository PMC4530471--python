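"""Exception hierarchy for structloc."""


class StructLocError(Exception):
    """Base class for all structloc errors."""


class FormatError(StructLocError):
    """A file could not be parsed in the expected format."""


class EmptySelectionError(StructLocError):
    """A selection (chain filter, atom subset) matched nothing."""


class SamplingError(StructLocError):
    """Grid/resolution combination violates sampling requirements."""


class UndefinedCorrelationError(StructLocError):
    """Correlation is undefined (empty mask or zero variance)."""


class DegenerateGeometryError(StructLocError):
    """Input geometry is degenerate (collinear points, empty grid, ...)."""


class UnderDeterminedError(StructLocError):
    """Too few constraints to determine a solution."""


class BuriedSiteError(StructLocError):
    """No sterically allowed probe positions around an attachment site."""


class FitFailureError(StructLocError):
    """A curve fit could not be performed on the supplied data."""
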