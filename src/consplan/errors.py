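"""Exception hierarchy for consplan.

Every error raised on purpose by the package derives from ConsplanError so
callers (and the sweep driver, which must survive per-scenario failures) can
catch package errors without swallowing programming mistakes.
"""


class ConsplanError(Exception):
    """Base class for all consplan errors."""


class ConfigError(ConsplanError):
    """Invalid configuration value (dimensions, CV targets, seed lists...)."""


class DimensionError(ConfigError):
    """Grid dimensions are non-positive or incompatible."""


class DegenerateInputError(ConsplanError):
    """Input too small or too uniform for the statistic to be defined."""


class AggregationError(ConsplanError):
    """Fine grid not divisible into whole planning-unit blocks."""


class GuildError(ConsplanError):
    """Unknown species guild label."""


class SpeciesError(ConsplanError):
    """Unknown species identifier."""


class UndefinedCVError(DegenerateInputError):
    """Coefficient of variation undefined (zero mean)."""


class UndefinedCorrelationError(DegenerateInputError):
    """Pearson correlation undefined (zero variance)."""


class SubsetError(ConsplanError):
    """Empty or invalid species subset."""


class NegativeCostError(ConsplanError):
    """A cost offset would push some unit cost to zero or below."""

    def __init__(self, delta: float, min_resulting_cost: float):
        self.delta = delta
        self.min_resulting_cost = min_resulting_cost
        super().__init__(
            f"offset delta={delta!r} drives the minimum unit cost to "
            f"{min_resulting_cost!r} <= 0; the requested relative CV exceeds "
            "what an additive shift can reach on this layer"
        )


class SolverError(ConsplanError):
    """The MILP backend failed for a reason other than infeasibility."""


class BruteForceGuardError(ConsplanError):
    """Instance too large for exhaustive enumeration."""


class DegenerateCurveError(ConsplanError):
    """Too few feasible points to integrate a cost-benefit curve."""


class BaselineError(ConsplanError):
    """Fractional gain undefined against a zero-efficiency baseline."""


class CalibrationError(ConsplanError):
    """A generator calibration search could not bracket its target."""
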