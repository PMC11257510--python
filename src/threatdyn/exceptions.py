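"""Exception hierarchy for threatdyn."""


class ThreatDynError(Exception):
    """Base class for all package-specific errors."""


class ScheduleOverflowError(ThreatDynError):
    """Raised when the requested trial schedule cannot fit into the scan."""


class InfeasibleConstraintError(ThreatDynError):
    """Raised when a constrained random draw has no feasible solution."""


class RankDeficiencyError(ThreatDynError):
    """Raised when a design matrix is (numerically) rank deficient.

    Carries the offending column labels in ``columns``.
    """

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class ExcessCensoringError(ThreatDynError):
    """Raised when more than half of the volumes are censored."""


class ZeroVarianceError(ThreatDynError):
    """Raised when a statistic requires non-zero variance."""


class IncompleteDesignError(ThreatDynError):
    """Raised when a repeated-measures table is missing cells."""


class IntegrationError(ThreatDynError):
    """Raised when numerical integration fails to converge."""


class EventsParseError(ThreatDynError):
    """Raised on malformed BIDS-style events files; carries the line number."""

    def __init__(self, message, line=None):
        super().__init__(message)
        self.line = line
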