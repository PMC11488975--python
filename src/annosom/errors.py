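"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`AnnosomError`, so callers (and the CLI) can catch one base class and
translate it into a non-zero exit code.
"""


class AnnosomError(Exception):
    """Base class for all errors raised by annosom."""


class ParseError(AnnosomError):
    """A file could not be parsed into the expected table."""


class DuplicateIdError(ParseError):
    """A cluster, sample or marker identifier occurs more than once."""


class EmptyInputError(ParseError):
    """An input file contains no data rows."""


class ValidationError(AnnosomError):
    """A table parsed fine but violates a semantic invariant."""


class NameClashError(ValidationError):
    """Two sibling phenotype nodes share a name."""


class ContradictionError(ValidationError):
    """A marker is required both positive and negative along one branch."""


class ZeroSampleError(ValidationError):
    """A sample has zero total cells; its proportions are undefined."""


class DegenerateMarkerError(AnnosomError):
    """A marker vector is too degenerate (constant, or too few distinct
    values) for threshold estimation."""


class UndefinedSilhouetteError(AnnosomError):
    """A binary partition has an empty side; its silhouette is undefined."""


class RangeError(AnnosomError, ValueError):
    """A numeric argument lies outside its documented range."""


class MissingThresholdError(AnnosomError, KeyError):
    """A marker used by the annotation tree has no threshold."""


class EmptyGroupError(AnnosomError):
    """A rank-sum test group is empty."""
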