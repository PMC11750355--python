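"""Exception hierarchy for the punctevo pipeline."""


class PunctevoError(Exception):
    """Base class for all package errors."""


class TreeFormatError(PunctevoError):
    """A tree file could not be parsed in the requested dialect."""


class TreeStructureError(PunctevoError):
    """A tree violates structural requirements (rooting, bifurcation)."""


class ConsistencyError(PunctevoError):
    """Trees in a posterior set do not share an identical tip-label set."""


class MetadataError(PunctevoError):
    """Tip metadata is missing or inconsistent with the tree."""


class ParameterError(PunctevoError):
    """A parameter is outside its admissible range."""


class DegenerateDataError(PunctevoError):
    """Input is degenerate for the requested computation (e.g. all-zero
    branch lengths, constant design column, monomorphic trait)."""


class DegenerateDesignError(DegenerateDataError):
    """The regression design matrix is singular; the fit is non-estimable."""
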