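"""Exception hierarchy.

Everything raised on invalid user input derives from both
:class:`FloretgenError` and :class:`ValueError`, so callers may catch
either.
"""


class FloretgenError(Exception):
    """Base class for all floretgen errors."""


class MorphologyError(FloretgenError, ValueError):
    """A segment list does not describe a valid rooted binary tree."""


class DuplicateIdError(MorphologyError):
    pass


class MissingRootError(MorphologyError):
    pass


class MultipleRootsError(MorphologyError):
    pass


class OrphanParentError(MorphologyError):
    """A segment references a parent id that does not exist."""


class CycleError(MorphologyError):
    """Segments unreachable from the root (cycle or disconnected part)."""


class UnaryBranchPointError(MorphologyError):
    """A segment has exactly one child; bifurcations must create two."""


class NonBinaryBranchingError(MorphologyError):
    """A node has more than two children."""


class UnknownSegmentError(MorphologyError, KeyError):
    pass


class SegmentTooShortError(MorphologyError):
    """A finalized floret contains a segment below the 1 micron floor."""


class MalformedSWCError(FloretgenError, ValueError):
    pass


class MissingColumnError(FloretgenError, ValueError):
    pass


class EmptyDatasetError(FloretgenError, ValueError):
    pass


class EmptySampleError(FloretgenError, ValueError):
    pass


class DegenerateSampleError(FloretgenError, ValueError):
    """All sample values identical where spread is required."""


class NonPositiveSampleError(FloretgenError, ValueError):
    pass


class SampleSizeError(FloretgenError, ValueError):
    pass


class InvalidParamsError(FloretgenError, ValueError):
    pass


class SupercriticalError(InvalidParamsError):
    """Galton-Watson parameters violate 2*p_branch + p_growth < 1."""


class InvalidFieldError(FloretgenError, ValueError):
    pass


class ZeroVectorError(FloretgenError, ValueError):
    pass


class IterationCapError(FloretgenError, RuntimeError):
    """A simulation exceeded its per-floret event cap."""
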