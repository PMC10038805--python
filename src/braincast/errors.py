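"""Exception hierarchy.

All braincast errors derive from :class:`BraincastError` so callers can
catch package failures with a single ``except`` clause.  Most also derive
from ``ValueError`` because they signal invalid inputs.
"""


class BraincastError(Exception):
    """Base class for all braincast errors."""


class InvalidParameterError(BraincastError, ValueError):
    """A configuration or generator parameter is out of its valid range."""


class InvalidInputError(BraincastError, ValueError):
    """An input object violates a precondition (empty, too small, ...)."""


class ShapeError(BraincastError, ValueError):
    """Two arrays that must be aligned have incompatible shapes."""


class AlignmentError(BraincastError, ValueError):
    """Word/token alignment failed (e.g. a word produced zero tokens)."""


class CoverageError(BraincastError, ValueError):
    """A word onset falls outside the scan grid."""


class InvalidSplitError(BraincastError, ValueError):
    """Cross-validation folds cannot be built (T < k)."""


class InvalidCurveError(BraincastError, ValueError):
    """A forecast curve does not cover the required distance grid."""


class InvalidLexiconError(BraincastError, ValueError):
    """A tagged lexicon violates its invariants (e.g. <2 words per tag pair)."""


class LexiconCoverageError(BraincastError, KeyError):
    """A (pos, dep) tag pair required for resampling is absent from the lexicon."""
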