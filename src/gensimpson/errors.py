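"""Exception and warning types shared across the package."""


class DiversityError(Exception):
    """Base class for all gensimpson errors."""


class InvalidCommunityError(DiversityError, ValueError):
    """Probability vector is not a valid community distribution."""


class InvalidOrderError(DiversityError, ValueError):
    """Entropy order r (or profile bound v) outside its valid range."""


class InvalidTransferError(DiversityError, ValueError):
    """Probability transfer violates the order-preserving constraints."""


class UndefinedVarianceError(DiversityError, ValueError):
    """Asymptotic variance is undefined (single observed species)."""


class DegenerateCommunityError(DiversityError, ValueError):
    """Operation undefined for a uniform (degenerate) community."""


class EnumerationBoundError(DiversityError, ValueError):
    """Exact enumeration refused: combinatorial size out of bounds."""


class AbundanceParseError(DiversityError, ValueError):
    """Abundance table could not be parsed."""


class DegenerateVarianceWarning(UserWarning):
    """Estimated p̂ is exactly uniform: σ̂ = 0, the normal CI degenerates."""


class OrderValidityWarning(UserWarning):
    """Order exceeds the estimated-richness bound r ≤ Ŝ − 1."""
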