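"""Exception hierarchy shared across the package."""


class Caliper3VVError(Exception):
    """Base class for all package errors."""


class MissingVessel(Caliper3VVError):
    """A required vessel class has no pixels in the mask."""

    def __init__(self, vessel: str):
        self.vessel = vessel
        super().__init__(f"no pixels of vessel class {vessel!r} in mask")


class DegenerateRegion(Caliper3VVError):
    """Region too small (or no admissible pixel pair) for the requested measurement."""


class InvalidDiameter(Caliper3VVError):
    """A diameter used in a ratio is non-positive."""


class InsufficientData(Caliper3VVError):
    """Not enough observations to estimate a cohort statistic."""


class DegenerateCohortWarning(UserWarning):
    """Cohort with zero ratio spread: the +/-2SD band collapses to a point."""


class ShapeMismatch(Caliper3VVError):
    """Ground-truth and predicted masks differ in shape."""


class UndefinedDice(Caliper3VVError):
    """Dice requested for a class absent from both masks (0/0)."""


class SingleClass(Caliper3VVError):
    """ROC analysis requires both normal and CHD labels."""


class EmptyInput(Caliper3VVError):
    """An aggregate was requested over an empty collection."""


class InvalidImage(Caliper3VVError):
    """Image does not satisfy the 8-bit grayscale contract."""


class OutOfCanvas(Caliper3VVError):
    """Requested ellipse does not fit the canvas."""


class OverlapError(Caliper3VVError):
    """Two rasterized vessels collide."""

    def __init__(self, first: str, second: str):
        self.pair = (first, second)
        super().__init__(f"rasterized vessels overlap: {first} and {second}")


class ParseError(Caliper3VVError):
    """Malformed detection line."""

    def __init__(self, path, line_no: int, message: str):
        self.path = path
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


class RangeError(ParseError):
    """Detection value outside its allowed range."""


class UnknownLabel(Caliper3VVError):
    """Mask PNG contains an index outside the label alphabet."""


class FormatError(Caliper3VVError):
    """File is not in the expected format."""
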