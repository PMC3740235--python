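"""Exception types shared across the package."""


class DynTexSegError(Exception):
    """Base class for all package-specific errors."""


class InsufficientFrames(DynTexSegError):
    """Temporal window provides fewer transitions than the model order."""


class DegenerateInput(DynTexSegError):
    """Mean-subtracted patch data has rank below the requested order."""


class OrderMismatch(DynTexSegError):
    """Two models cannot be compared (different order or patch size)."""


class WindowOutOfRange(DynTexSegError):
    """Requested temporal window does not fit inside the sequence."""


class EmptyRegion(DynTexSegError):
    """Operation requires a nonempty pixel region."""


class EmptySamples(DynTexSegError):
    """Operation requires at least one sampled model."""


class MissingStats(DynTexSegError):
    """Energy evaluation requires region statistics that were not supplied."""


class GridMismatch(DynTexSegError):
    """Two model fields do not share grid geometry."""


class DegenerateMask(DynTexSegError):
    """Mask too small or collinear for rectangle fitting."""


class NumericalBlowup(DynTexSegError):
    """A level-set field became non-finite (step size too large)."""


class DegeneratePolygon(DynTexSegError):
    """Polygon has fewer than three vertices or zero area."""


class SequenceTooShort(DynTexSegError):
    """Sequence shorter than one temporal window."""


class ZeroReference(DynTexSegError):
    """Reference series sums to zero; normalization undefined."""


class ShapeMismatch(DynTexSegError):
    """Arrays being compared do not share a shape."""


class UnreadableFile(DynTexSegError):
    """A frame file could not be read."""


class MixedBitDepth(DynTexSegError):
    """Frame files mix different bit depths."""


class EmptyDirectory(DynTexSegError):
    """A frame directory contains no readable frames."""
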