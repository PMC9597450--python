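"""Exception hierarchy shared across the package."""


class SesamedivError(Exception):
    """Base class for all package errors."""


class MalformedCellError(SesamedivError):
    """A band-matrix cell is not 0 or 1; message names the row and column."""


class DuplicateBandError(SesamedivError):
    """Two records share the same (assay_id, band_id) key."""


class EmptyInputError(SesamedivError):
    """An input file or table contains no records."""


class InsufficientGenotypesError(SesamedivError):
    """An operation needs at least two genotypes."""


class LookupError_(SesamedivError):
    """An assay, locus, genotype or population label is unknown."""


class UndefinedStatisticError(SesamedivError):
    """A statistic is undefined for the given input (e.g. TAB = 0)."""


class DomainError(SesamedivError):
    """A numeric argument lies outside its mathematical domain."""


class DegenerateChromosomeError(SesamedivError):
    """A chromosome has zero total length."""


class UndefinedCVError(SesamedivError):
    """Coefficient-of-variation indices need at least two chromosomes."""


class FeasibilityError(SesamedivError):
    """A synthetic-data specification cannot be realised."""


class ParameterError(SesamedivError):
    """A parameter value is outside its allowed range."""


class ValidationError(SesamedivError):
    """A matrix fails a structural requirement (symmetry, size, roster)."""
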