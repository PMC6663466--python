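"""Exception hierarchy used across the package."""


class AsorPipeError(Exception):
    """Base class for all package errors."""


class LayoutCapacityError(AsorPipeError):
    """More genes than candidate wells available in the plate set."""


class WindowRangeError(AsorPipeError):
    """A trace does not cover the requested slope-search window."""


class DegenerateWindowError(AsorPipeError):
    """Fewer than one full regression window fits inside the search range."""


class DegenerateDispersionError(AsorPipeError):
    """Plate MAD is zero; robust Z-scores are undefined."""


class ZeroReferenceError(AsorPipeError):
    """Background-subtracted fluorescence is zero at the normalization reference time."""


class UnknownIonError(AsorPipeError):
    """An ion species is not in the valence registry."""


class SolutionError(AsorPipeError):
    """Invalid solution composition (negative concentration, bad pH...)."""


class NoRootError(AsorPipeError):
    """The summed GHK current has no sign change on the search bracket."""


class DivalentIonError(AsorPipeError):
    """Bi-ionic permeability ratios are only defined for monovalent anions;
    report the reversal-potential shift instead."""


class InsufficientDataError(AsorPipeError):
    """Not enough distinct data points for the requested fit."""


class TableFormatError(AsorPipeError):
    """A CSV/TSV input violates the expected schema."""


class MismatchError(AsorPipeError):
    """Trace table and plate layout disagree about a well."""
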