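"""Exception hierarchy for beatsync.

All errors raised by the package derive from :class:`BeatSyncError` so callers
can catch everything with one handler while still distinguishing schema
problems from numerical degeneracies.
"""


class BeatSyncError(Exception):
    """Base class for all beatsync errors."""


class SchemaError(BeatSyncError):
    """An input table is missing a required column or has the wrong layout."""


class TrialValidationError(BeatSyncError):
    """A trial's rows violate an invariant (non-monotonic times, duplicates)."""


class DomainError(BeatSyncError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class DegenerateDirectionError(DomainError):
    """The mean resultant vector is (numerically) zero: no mean direction."""


class FitError(BeatSyncError):
    """A distribution fit could not be performed (too few observations)."""


class SimulationError(BeatSyncError):
    """Monte Carlo generation failed (e.g. rejection sampling exhausted)."""
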