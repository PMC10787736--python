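"""Exception hierarchy for npnamematch.

Every error raised by the library derives from :class:`NpNameMatchError`,
so callers can catch one base class at pipeline boundaries.
"""


class NpNameMatchError(Exception):
    """Base class for all npnamematch errors."""


class EmptyAfterCleaning(NpNameMatchError):
    """No alphabetic character survived cleaning (e.g. input ``"123!!"``)."""


class TooLong(NpNameMatchError):
    """A cleaned name exceeds the fixed encoding length."""


class InvalidCode(NpNameMatchError):
    """An integer sequence violates the encoding invariants."""


class BothEmpty(NpNameMatchError):
    """Normalized Levenshtein distance is undefined for two empty strings."""


class DegenerateName(NpNameMatchError):
    """Perturbation repeatedly produced an unusable (empty/over-long) string."""


class InsufficientGroups(NpNameMatchError):
    """Non-matching pairs were requested but the lexicon has a single group."""


class TooFewPairs(NpNameMatchError):
    """Not enough pairs to carve out the requested holdout set."""


class ZeroVector(NpNameMatchError):
    """Cosine distance is undefined when either vector has zero norm."""


class InvalidConfig(NpNameMatchError):
    """A model configuration violates its invariants."""


class IncompatibleManifest(NpNameMatchError):
    """A saved model's manifest disagrees with the current configuration/code."""


class ModelMissing(NpNameMatchError):
    """The Siamese method was requested without supplying a model."""


class EmptyOutcomes(NpNameMatchError):
    """Mean reciprocal rank over an empty outcome list."""


class DegenerateMarginals(NpNameMatchError):
    """Cohen's kappa is undefined when chance agreement equals 1."""


class UnreviewedCandidates(NpNameMatchError):
    """Overlap accounting requires every candidate to be annotated."""


class SchemaMismatch(NpNameMatchError):
    """An annotation sheet does not conform to the expected schema."""
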