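"""Exception types shared across the package."""


class PhonohppError(Exception):
    """Base class for package errors."""


class LexiconFormatError(PhonohppError):
    """A lexicon file does not match the declared dialect (missing column, bad row)."""


class LexiconValidationError(PhonohppError):
    """A lexicon entry violates the phoneme inventory or another invariant."""


class EmptyLexiconError(PhonohppError):
    """A lexicon or corpus contains no usable entries."""


class DesignError(PhonohppError):
    """A stimulus-design request is infeasible or a generated design is invalid."""


class SimulationError(PhonohppError):
    """Invalid simulation parameters."""


class AnalysisError(PhonohppError):
    """Looking-time analysis cannot proceed (no retained participants, bad rows, ...)."""
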