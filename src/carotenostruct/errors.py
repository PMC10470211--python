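"""Exception hierarchy for carotenostruct."""


class CarotenostructError(Exception):
    """Base class for all package errors."""


class FormatError(CarotenostructError):
    """A structure or table file could not be parsed."""


class DimerSelectionError(CarotenostructError):
    """No heterodimer could be identified in the structure."""


class LigandMatchError(CarotenostructError):
    """A ligand residue matched more than one template."""


class MissingAtomError(CarotenostructError):
    """A template atom has no counterpart in the coordinates."""


class DegenerateGeometryError(CarotenostructError):
    """Collinear or otherwise degenerate input to a geometric fit."""


class ScopeError(CarotenostructError):
    """A bond-length-alternation scope contains no usable bonds."""


class UnknownElementError(CarotenostructError):
    """No van der Waals radius or isotope mass for an element."""


class NoPeakError(CarotenostructError):
    """No interior absorbance maximum found in the search range."""


class SequenceError(CarotenostructError):
    """Invalid amino-acid sequence or annotation."""


class FormulaError(CarotenostructError):
    """A molecular formula string could not be parsed."""


class SyntheticSpecError(CarotenostructError):
    """Inconsistent parameters for a synthetic-data generator."""
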