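"""Exception hierarchy shared by all indikit modules."""


class IndikitError(Exception):
    """Base class for all indikit errors."""


# --- alignment / consensus ---------------------------------------------------

class AlignmentFormatError(IndikitError):
    """Sequences of unequal length, invalid symbols, or otherwise malformed MSA."""


class MissingReferenceError(IndikitError):
    """The designated reference identifier is absent from the alignment."""


class EmptyInputError(IndikitError):
    """An input file or collection contained no records."""


class EmptyHomologSetError(IndikitError):
    """No homolog survived the identity filter."""


# --- structures --------------------------------------------------------------

class StructureParseError(IndikitError):
    """A coordinate file could not be parsed."""


class EmptyStructureError(IndikitError):
    """A coordinate file contained no ATOM records."""


class DegenerateBFactorError(IndikitError):
    """All B-factors equal: z-normalization undefined."""


class DegenerateGeometryError(IndikitError):
    """Too few or collinear points for a rigid superposition."""


# --- curve fitting -----------------------------------------------------------

class NoTransitionError(IndikitError):
    """A melt curve shows no rising unfolding transition."""


class FitFailureError(IndikitError):
    """Nonlinear least squares failed to converge."""


class DegenerateDesignError(IndikitError):
    """A regression design with no spread in the predictor."""


class InputError(IndikitError):
    """Invalid numerical input to an analysis operation."""


# --- techno-economics --------------------------------------------------------

class MissingPriceError(IndikitError):
    """A recipe item has no entry in the price table."""


class DegenerateRecipeError(IndikitError):
    """A recipe producing zero product mass."""


class UnknownParameterError(IndikitError):
    """A sensitivity/breakeven parameter path does not resolve."""


class DistributionError(IndikitError):
    """Invalid price-distribution parameters."""


class NoSolutionError(IndikitError):
    """Breakeven target not bracketed by the parameter bounds."""


# --- colorimetry -------------------------------------------------------------

class CoverageError(IndikitError):
    """A spectrum does not cover the requested wavelength grid."""


class GridMismatchError(IndikitError):
    """Spectral tables are not on a common wavelength grid."""


class InsufficientSampleError(IndikitError):
    """Too few samples for the requested population statistics."""


# --- synthetic data ----------------------------------------------------------

class InfeasibleSpecError(IndikitError):
    """A generator specification that cannot be satisfied."""
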