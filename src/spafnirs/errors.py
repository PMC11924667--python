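"""Exception types raised across the pipeline."""


class SpaFnirsError(Exception):
    """Base class for all package-specific errors."""


class ScheduleInfeasibleError(SpaFnirsError):
    """The session is too short to place all trials with the minimum ISI."""


class InvalidInputError(SpaFnirsError):
    """An input violated a documented precondition (e.g. non-positive intensity)."""


class RankDeficiencyError(SpaFnirsError):
    """A design matrix is rank deficient; the message lists collinear columns."""


class NoEpochsError(SpaFnirsError):
    """No usable epochs remained for a condition."""
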