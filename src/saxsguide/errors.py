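"""Exception hierarchy shared across the package."""


class SaxsGuideError(Exception):
    """Base class for all domain errors raised by saxsguide."""


class GridMismatchError(SaxsGuideError):
    """Two profiles live on different q grids and interpolation is disabled."""


class GuinierFitError(SaxsGuideError):
    """Guinier analysis failed (positive low-q slope or too few points)."""


class ConnectivityError(SaxsGuideError):
    """A Markov chain lacks the connectivity required by the operation."""


class PDBFormatError(SaxsGuideError):
    """A fixed-column coordinate record could not be parsed."""
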