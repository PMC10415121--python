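"""Exception hierarchy.

All recoverable toolkit failures derive from :class:`RibocircError` so the
CLI can map them to exit status 1 while genuine bugs propagate.
"""


class RibocircError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(RibocircError, ValueError):
    """A symbol outside the declared nucleotide alphabet was encountered."""


class TopologyError(RibocircError, ValueError):
    """An operation required circular (or linear) topology and got the other."""


class SpecError(RibocircError, ValueError):
    """A fixture specification is internally unsatisfiable."""


class NoSpliceSiteFound(RibocircError):
    """Exact-mode junction selection failed: the target contains no U."""


class DesignError(RibocircError):
    """A design constraint could not be met (or a DesignWarning under strict)."""


class DesignWarning(UserWarning):
    """A soft design-quality issue (e.g. weak P10 pairing); error under strict."""


class FrameError(RibocircError, ValueError):
    """A coding-sequence operation would break the reading frame."""


class ValidationError(RibocircError, ValueError):
    """Input failed a structural validation (bad ORF, bad table, ...)."""


class AnnotationError(RibocircError):
    """A construct is missing features required by the requested operation."""


class DesignInconsistency(RibocircError):
    """Annotated splice sites disagree with the IGS pairing geometry."""


class DataError(RibocircError, ValueError):
    """A quantification table is malformed or incomplete."""


class ConsistencyError(RibocircError, ValueError):
    """Numerically impossible assay input (e.g. circRNA exceeding total RNA)."""
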