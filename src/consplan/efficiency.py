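"""Cost-benefit curves and AUC efficiency comparison.

A cost-benefit curve records, for an ascending ladder of occupancy
targets (5-100% in 5% steps), the monetary cost of the solution as a
fraction of the total cost of all planning units in the scenario's cost
layer. Steeper curves — higher targets reached at lower cost — are more
efficient. Efficiency is summarized as the area under achieved-target
(y) versus cost-fraction (x): every curve is anchored at the origin and
the last feasible point is extended horizontally to cost fraction 1, so
a curve reaching the full target at negligible cost has AUC -> 1 and
curves with different feasible support remain comparable. The transposed
orientation (area under cost versus target, lower = better) is available
as an option.

The fractional gain in efficiency of scenario A over baseline B is
(AUC_A - AUC_B) / AUC_B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .aggregation import PlanningUnitTable
from .errors import BaselineError, ConfigError, DegenerateCurveError
from .prioritize import (
    DEFAULT_GAP,
    Denominator,
    ProblemSpec,
    Solution,
    crank_select,
    solve_min_set,
)

Method = Literal["min_cost", "min_area", "crank"]
AucOrientation = Literal["target_vs_cost", "cost_vs_target"]

#: the standard occupancy-target ladder: 5-100% in 5% increments
TARGET_LADDER: tuple[float, ...] = tuple(
    round(0.05 * k, 2) for k in range(1, 21))


@dataclass(frozen=True)
class CostBenefitCurve:
    """Cost fraction versus occupancy target for one scenario."""

    targets: tuple[float, ...]
    cost_fraction: tuple[float, ...]   # nan where infeasible
    feasible: tuple[bool, ...]
    monetary_cost: tuple[float, ...]
    total_cost: float
    guild: str | None = None
    threshold: float | None = None
    cv_relative: float | None = None
    method: str | None = None

    def __post_init__(self) -> None:
        n = len(self.targets)
        if not (len(self.cost_fraction) == len(self.feasible)
                == len(self.monetary_cost) == n):
            raise ConfigError("curve field lengths differ")

    def feasible_prefix(self) -> tuple[np.ndarray, np.ndarray]:
        """(targets, cost_fractions) up to the first infeasible point."""
        feas = np.asarray(self.feasible, dtype=bool)
        k = int(np.argmin(feas)) if not feas.all() else len(feas)
        return (np.asarray(self.targets[:k], dtype=float),
                np.asarray(self.cost_fraction[:k], dtype=float))

    def to_records(self) -> list[dict]:
        return [
            {"guild": self.guild, "threshold": self.threshold,
             "cv_relative": self.cv_relative, "method": self.method,
             "target": t, "cost_fraction": cf, "monetary_cost": mc,
             "feasible": fe, "total_cost": self.total_cost}
            for t, cf, mc, fe in zip(self.targets, self.cost_fraction,
                                     self.monetary_cost, self.feasible)
        ]


@dataclass(frozen=True)
class EfficiencyResult:
    """AUC of one or more curves plus named fractional gains."""

    auc: dict
    comparisons: dict


def _solve_for_method(units: PlanningUnitTable, subset, target: float,
                      threshold: float, method: Method, gap: float,
                      denominator: Denominator,
                      time_limit: float | None) -> Solution:
    mode = "unit_count" if method == "min_area" else "monetary_cost"
    spec = ProblemSpec(units=units, species_subset=subset,
                       target_fraction=target,
                       occupancy_threshold=threshold,
                       objective_mode=mode, optimality_gap=gap,
                       denominator=denominator, time_limit=time_limit)
    return crank_select(spec) if method == "crank" else solve_min_set(spec)


def build_curve(units: PlanningUnitTable, guild: str, threshold: float,
                method: Method, gap: float = DEFAULT_GAP,
                targets: Sequence[float] = TARGET_LADDER,
                denominator: Denominator = "post_threshold",
                cv_relative: float | None = None,
                time_limit: float | None = None) -> CostBenefitCurve:
    """One solution per target on the ladder, costed monetarily.

    min_area solutions minimize unit count but are costed monetarily
    afterwards, so with- and without-cost scenarios share a currency.
    Infeasible targets are flagged, never raised.
    """
    if method not in ("min_cost", "min_area", "crank"):
        raise ConfigError(f"unknown method {method!r}")
    subset = units.guild_species(guild)
    total = float(units.cost.sum())
    fractions, feasible, costs = [], [], []
    for t in targets:
        sol = _solve_for_method(units, subset, t, threshold, method, gap,
                                denominator, time_limit)
        if sol.feasible:
            fractions.append(sol.monetary_cost / total)
            costs.append(sol.monetary_cost)
            feasible.append(True)
        else:
            fractions.append(float("nan"))
            costs.append(float("nan"))
            feasible.append(False)
    return CostBenefitCurve(targets=tuple(float(t) for t in targets),
                            cost_fraction=tuple(fractions),
                            feasible=tuple(feasible),
                            monetary_cost=tuple(costs),
                            total_cost=total, guild=guild,
                            threshold=threshold, cv_relative=cv_relative,
                            method=method)


def curve_auc(curve: CostBenefitCurve,
              orientation: AucOrientation = "target_vs_cost",
              max_target: float | None = None) -> float:
    """Trapezoidal AUC of the curve's feasible prefix.

    target_vs_cost (default): area under achieved target as a function of
    cost fraction, origin-anchored, last point extended to cost fraction
    1; higher is more efficient, range [0, 1]. cost_vs_target: area under
    cost fraction as a function of target; lower is more efficient.
    ``max_target`` restricts the prefix (for comparisons on common
    support).
    """
    t, x = curve.feasible_prefix()
    if max_target is not None:
        keep = t <= max_target + 1e-12
        t, x = t[keep], x[keep]
    if len(t) < 2:
        raise DegenerateCurveError(
            "need at least 2 feasible points to integrate")
    t = np.concatenate([[0.0], t])
    x = np.concatenate([[0.0], x])
    if orientation == "cost_vs_target":
        return float(np.trapezoid(x, t))
    if orientation != "target_vs_cost":
        raise ConfigError(f"unknown orientation {orientation!r}")
    if x[-1] < 1.0:  # benefit already banked; extend to full cost axis
        t = np.concatenate([t, [t[-1]]])
        x = np.concatenate([x, [1.0]])
    return float(np.trapezoid(t, x))


def fractional_gain(auc_with: float, auc_without: float) -> float:
    """Relative AUC improvement of one scenario over a baseline."""
    if auc_without <= 0:
        raise BaselineError("baseline AUC must be > 0")
    return (auc_with - auc_without) / auc_without


def common_max_target(*curves: CostBenefitCurve) -> float:
    """Largest target feasible in every curve's feasible prefix."""
    maxes = []
    for c in curves:
        t, _ = c.feasible_prefix()
        if len(t) == 0:
            return 0.0
        maxes.append(t[-1])
    return float(min(maxes))


def compare_curves(curves: dict[str, CostBenefitCurve],
                   orientation: AucOrientation = "target_vs_cost",
                   ) -> EfficiencyResult:
    """AUCs on common feasible support plus the two standard comparisons:

    * ``gain_cost_data``: min_cost over min_area (value of adding the
      cost layer to a biodiversity-driven prioritization);
    * ``gain_biodiversity_data``: min_cost over crank (value of adding
      biodiversity data to a cost-driven one).
    """
    mt = common_max_target(*curves.values())
    auc = {name: curve_auc(c, orientation, max_target=mt)
           for name, c in curves.items()}
    comparisons = {}
    if "min_cost" in auc and "min_area" in auc:
        comparisons["gain_cost_data"] = fractional_gain(
            auc["min_cost"], auc["min_area"])
    if "min_cost" in auc and "crank" in auc:
        comparisons["gain_biodiversity_data"] = fractional_gain(
            auc["min_cost"], auc["crank"])
    return EfficiencyResult(auc=auc, comparisons=comparisons)
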