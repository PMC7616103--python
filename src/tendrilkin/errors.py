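"""Exception hierarchy for tendrilkin."""


class TendrilkinError(Exception):
    """Base class for all package errors."""


class FormatError(TendrilkinError):
    """A file does not conform to the documented dialect."""


class TrajectoryValidationError(TendrilkinError):
    """A trajectory violates an invariant (non-monotone clock, too short, ...)."""


class UnsupportedConditionError(TendrilkinError):
    """The requested measure is undefined for this condition (e.g. no-support plants
    have no stimulus distance and no grasping phase)."""


class InsufficientDataError(TendrilkinError):
    """Too few samples inside the requested analysis window."""


class ContractError(TendrilkinError, ValueError):
    """Caller violated a function precondition (length mismatch, bad enum, ...)."""
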