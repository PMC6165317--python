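"""Exception hierarchy for the shade-matching pipeline."""


class ShadeMatchError(Exception):
    """Base class for all shadematch errors."""


class DomainError(ShadeMatchError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class CalibrationError(ShadeMatchError, ValueError):
    """Color-correction fitting failed (rank deficiency, length mismatch)."""


class SegmentationError(ShadeMatchError, RuntimeError):
    """A segmentation stage could not produce a usable region."""


class IntegrityError(ShadeMatchError, ValueError):
    """Duplicate or inconsistent records in the measurement database."""


class ValidationError(ShadeMatchError, ValueError):
    """Malformed labels, features, or configuration."""


class MatchingError(ShadeMatchError, ValueError):
    """Shade matching or classifier training could not proceed."""


class StateError(ShadeMatchError, RuntimeError):
    """An object was used before being put into the required state."""
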