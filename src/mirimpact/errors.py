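"""Exception hierarchy for mirimpact.

All package-specific failures derive from :class:`MirImpactError` so callers
can catch one base class at pipeline boundaries.
"""


class MirImpactError(Exception):
    """Base class for all mirimpact errors."""


class FormatError(MirImpactError):
    """A file violates its declared on-disk format (duplicates, short lines)."""


class ConsistencyError(MirImpactError):
    """In-memory objects violate a structural invariant (ID/shape mismatch)."""


class PackagingError(MirImpactError):
    """A packaged data fixture is missing or corrupt."""


class ConfigError(MirImpactError):
    """A simulation configuration is infeasible or self-contradictory."""


class InputError(MirImpactError):
    """An operation received statistically unusable input (empty group, ...)."""


class EstimationError(MirImpactError):
    """A hyperparameter estimation step cannot proceed."""


class DegenerateBackgroundError(MirImpactError):
    """A resampled background has zero spread and cannot standardize a score."""
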