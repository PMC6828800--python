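"""Reserve-selection problems: minimum-set ILP, cost-rank greedy, oracle.

The minimum set problem selects a subset of planning units minimizing
total weight (monetary cost, or unit count for the minimum-area variant)
subject to capturing, for every species in the active subset, at least a
target fraction of that species' total occupancy. A unit counts toward a
species only where its mean occupancy meets the habitat-suitability
threshold (inclusive, per species); below-threshold occupancy contributes
a zero coefficient, not unit removal, so one unit can serve one species
but not another.

The ILP is solved exactly (to a relative optimality gap, default 1%) with
the HiGHS branch-and-bound backend via scipy. The C-rank baseline buys
units cheapest-first — using biodiversity data only to detect when targets
are met — and the brute-force oracle enumerates every subset on small
instances for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.stats import pearsonr

from .aggregation import PlanningUnitTable
from .errors import (
    BruteForceGuardError,
    ConfigError,
    SolverError,
    SubsetError,
    UndefinedCorrelationError,
)

ObjectiveMode = Literal["monetary_cost", "unit_count"]
Denominator = Literal["post_threshold", "pre_threshold"]

# slack accepted when judging a species target met; covers float summation
# order, nothing more
_FEAS_TOL = 1e-9

DEFAULT_GAP = 0.01  # solve to within 1% of the optimum by default


@dataclass(frozen=True)
class ProblemSpec:
    """One prioritization instance.

    target_fraction is the common per-species target (fraction of total
    occupancy to capture); occupancy_threshold excludes units as habitat
    per species; denominator chooses whether species totals are taken over
    eligible (post-threshold, default) or all (pre-threshold) units.
    """

    units: PlanningUnitTable
    species_subset: tuple[str, ...]
    target_fraction: float
    occupancy_threshold: float = 0.0
    objective_mode: ObjectiveMode = "monetary_cost"
    optimality_gap: float = DEFAULT_GAP
    denominator: Denominator = "post_threshold"
    time_limit: float | None = None  # solver wall-clock cap, seconds

    def __post_init__(self) -> None:
        if not self.species_subset:
            raise SubsetError("species_subset must be non-empty")
        for s in self.species_subset:
            self.units.species_index(s)  # raises SpeciesError if unknown
        if not 0 < self.target_fraction <= 1:
            raise ConfigError("target_fraction must lie in (0, 1]")
        if not 0 <= self.occupancy_threshold < 1:
            raise ConfigError("occupancy_threshold must lie in [0, 1)")
        if self.objective_mode not in ("monetary_cost", "unit_count"):
            raise ConfigError(f"unknown objective_mode {self.objective_mode!r}")
        if self.optimality_gap < 0:
            raise ConfigError("optimality_gap must be >= 0")
        if self.denominator not in ("post_threshold", "pre_threshold"):
            raise ConfigError(f"unknown denominator {self.denominator!r}")
        if self.time_limit is not None and self.time_limit <= 0:
            raise ConfigError("time_limit must be positive when set")

    # --- threshold filtering -------------------------------------------

    def masked_occupancy(self, species_id: str) -> np.ndarray:
        """Occupancy column with below-threshold entries zeroed."""
        occ = self.units.occupancy[self.units.species_index(species_id)]
        return np.where(occ >= self.occupancy_threshold, occ, 0.0)

    def constraint_matrix(self) -> np.ndarray:
        """(n_species_subset, n_units) matrix of eligible occupancies."""
        return np.stack([self.masked_occupancy(s)
                         for s in self.species_subset])

    def objective_weights(self) -> np.ndarray:
        if self.objective_mode == "monetary_cost":
            return self.units.cost.astype(float)
        return np.ones(self.units.n_units)

    def target_amounts(self) -> np.ndarray:
        """Per-species absolute occupancy amounts to capture."""
        return self.target_fraction * np.array(
            [species_total(self, s) for s in self.species_subset])


@dataclass(frozen=True)
class Solution:
    """A selected unit set with its accounting."""

    selected: tuple[int, ...]
    objective_value: float
    monetary_cost: float
    representation: dict
    status: Literal["optimal_within_gap", "infeasible", "time_limit_feasible"]
    solver_gap_reported: float

    @property
    def feasible(self) -> bool:
        return self.status != "infeasible"

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "objective_value": self.objective_value,
            "monetary_cost": self.monetary_cost,
            "representation": self.representation,
            "status": self.status,
            "solver_gap_reported": self.solver_gap_reported,
        }


def eligible_units(spec: ProblemSpec, species_id: str) -> np.ndarray:
    """Unit ids whose occupancy for the species meets the threshold
    (inclusive comparison)."""
    occ = spec.units.occupancy[spec.units.species_index(species_id)]
    return np.flatnonzero(occ >= spec.occupancy_threshold)


def species_total(spec: ProblemSpec, species_id: str) -> float:
    """The target denominator: the species' total occupancy, summed over
    eligible units (post-threshold, default) or all units (pre-threshold).
    """
    occ = spec.units.occupancy[spec.units.species_index(species_id)]
    if spec.denominator == "pre_threshold":
        return float(occ.sum())
    return float(occ[occ >= spec.occupancy_threshold].sum())


def _representation(spec: ProblemSpec, selected: np.ndarray) -> dict:
    rep = {}
    for s in spec.species_subset:
        masked = spec.masked_occupancy(s)
        captured = float(masked[selected].sum()) if selected.size else 0.0
        total = species_total(spec, s)
        rep[s] = {
            "captured": captured,
            "total": total,
            "fraction": captured / total if total > 0 else 0.0,
        }
    return rep


def _make_solution(spec: ProblemSpec, selected: np.ndarray,
                   status: str, gap: float) -> Solution:
    selected = np.sort(np.asarray(selected, dtype=int))
    weights = spec.objective_weights()
    return Solution(
        selected=tuple(int(i) for i in selected),
        objective_value=float(weights[selected].sum()),
        monetary_cost=float(spec.units.cost[selected].sum()),
        representation=_representation(spec, selected),
        status=status, solver_gap_reported=float(gap),
    )


def _infeasible(spec: ProblemSpec) -> Solution:
    return _make_solution(spec, np.array([], dtype=int), "infeasible",
                          float("nan"))


def _unreachable_targets(spec: ProblemSpec, amounts: np.ndarray,
                         A: np.ndarray) -> bool:
    """True when some target exceeds what all eligible units together can
    supply — including the empty-eligible-set case, which is infeasible
    even under the post-threshold denominator (nothing suitable exists)."""
    supply = A.sum(axis=1)
    tol = _FEAS_TOL * np.maximum(1.0, np.abs(amounts))
    return bool(np.any(supply <= 0) or np.any(amounts > supply + tol))


def solve_min_set(spec: ProblemSpec) -> Solution:
    """Solve the minimum-set ILP.

    minimize sum_i w_i x_i  subject to, per species s,
    sum_i p_si x_i >= target_fraction * total_s, x_i binary,
    with w the unit costs (monetary_cost mode) or all ones (unit_count).
    Solved to within ``spec.optimality_gap`` relative gap. Infeasibility is
    returned as a status, never raised; backend failures raise SolverError.

    A ``time_limit`` on the spec caps the branch-and-bound wall clock:
    near-uniform cost layers (large relative-CV offsets) can make the
    bound proof — not the solution — arbitrarily slow. At the cap the
    incumbent is returned with its achieved gap in solver_gap_reported
    and, if that gap exceeds the requested one, status
    "time_limit_feasible" instead of "optimal_within_gap".
    """
    A = spec.constraint_matrix()
    amounts = spec.target_amounts()
    if _unreachable_targets(spec, amounts, A):
        return _infeasible(spec)
    # deflate targets by the feasibility slack so that e.g. a 100% target,
    # met exactly by the full eligible set, is not lost to rounding
    lb = amounts - _FEAS_TOL * np.maximum(1.0, np.abs(amounts))
    weights = spec.objective_weights()
    options: dict = {"mip_rel_gap": float(spec.optimality_gap)}
    if spec.time_limit is not None:
        options["time_limit"] = float(spec.time_limit)
    res = milp(
        c=weights / weights.mean(),  # scale-invariant; helps conditioning
        constraints=LinearConstraint(A, lb=lb, ub=np.inf),
        integrality=np.ones(spec.units.n_units),
        bounds=Bounds(0, 1),
        options=options,
    )
    if res.status == 2:  # problem infeasible
        return _infeasible(spec)
    hit_limit = res.status == 1 and res.x is not None
    if not (res.success or hit_limit) or res.x is None:
        raise SolverError(f"MILP backend failed: status={res.status} "
                          f"({res.message})")
    selected = np.flatnonzero(res.x > 0.5)
    gap = float(res.mip_gap) if res.mip_gap is not None else 0.0
    status = ("optimal_within_gap"
              if gap <= spec.optimality_gap + 1e-12
              else "time_limit_feasible")
    sol = _make_solution(spec, selected, status, gap)
    return _repair_shortfall(spec, sol, amounts)


def _repair_shortfall(spec: ProblemSpec, sol: Solution,
                      amounts: np.ndarray) -> Solution:
    """Top up a solver solution that misses a target by more than the
    package feasibility slack (possible at loose backend tolerances):
    greedily add the cheapest unit helping a short species."""
    short = [i for i, s in enumerate(spec.species_subset)
             if sol.representation[s]["fraction"]
             < spec.target_fraction - _FEAS_TOL]
    if not short:
        return sol
    selected = set(sol.selected)
    A = spec.constraint_matrix()
    weights = spec.objective_weights()
    order = np.lexsort((np.arange(spec.units.n_units), weights))
    captured = A[:, list(selected)].sum(axis=1) if selected else \
        np.zeros(len(spec.species_subset))
    tol = _FEAS_TOL * np.maximum(1.0, np.abs(amounts))
    for i in order:
        if np.all(captured >= amounts - tol):
            break
        if i in selected:
            continue
        if np.any((A[:, i] > 0) & (captured < amounts - tol)):
            selected.add(int(i))
            captured = captured + A[:, i]
    return _make_solution(spec, np.array(sorted(selected)),
                          sol.status, sol.solver_gap_reported)


def crank_select(spec: ProblemSpec) -> Solution:
    """Cheapest-first (C-rank) selection.

    Units are added in ascending cost order (ties by ascending unit id)
    until every species target is met; biodiversity data is used only to
    detect satisfaction. Target accounting uses the same eligibility rule
    as the ILP.
    """
    A = spec.constraint_matrix()
    amounts = spec.target_amounts()
    if _unreachable_targets(spec, amounts, A):
        return _infeasible(spec)
    order = np.lexsort((np.arange(spec.units.n_units), spec.units.cost))
    cum = np.cumsum(A[:, order], axis=1)
    tol = _FEAS_TOL * np.maximum(1.0, np.abs(amounts))
    met = np.all(cum >= (amounts - tol)[:, None], axis=0)
    if not met.any():
        return _infeasible(spec)
    k = int(np.argmax(met))
    return _make_solution(spec, order[:k + 1], "optimal_within_gap", 0.0)


def brute_force_min_set(spec: ProblemSpec, max_units: int = 20) -> Solution:
    """Exhaustive-enumeration oracle for small instances (<= max_units).

    Returns the feasible subset minimizing the objective; exact ties are
    broken by the lexicographically smallest selected-id tuple.
    """
    n = spec.units.n_units
    if n > max_units:
        raise BruteForceGuardError(
            f"{n} units exceeds the enumeration guard ({max_units})")
    A = spec.constraint_matrix()
    amounts = spec.target_amounts()
    if _unreachable_targets(spec, amounts, A):
        return _infeasible(spec)
    weights = spec.objective_weights()
    masks = np.arange(1, 2**n, dtype=np.int64)
    bits = ((masks[:, None] >> np.arange(n)) & 1).astype(float)
    coverage = bits @ A.T
    tol = _FEAS_TOL * np.maximum(1.0, np.abs(amounts))
    feasible = np.all(coverage >= amounts - tol, axis=1)
    if not feasible.any():
        return _infeasible(spec)
    objective = bits @ weights
    objective[~feasible] = np.inf
    best = objective.min()
    candidates = np.flatnonzero(objective <= best)
    best_sel = min(tuple(np.flatnonzero(bits[i])) for i in candidates)
    return _make_solution(spec, np.array(best_sel, dtype=int),
                          "optimal_within_gap", 0.0)


def cost_correlation(units: PlanningUnitTable, species_id: str) -> float:
    """Pearson correlation between a species' occupancy and unit cost."""
    occ = units.occupancy[units.species_index(species_id)]
    if units.n_units < 3:
        raise UndefinedCorrelationError("need at least 3 units")
    if np.std(occ) == 0 or np.std(units.cost) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined for zero-variance input")
    return float(pearsonr(occ, units.cost).statistic)
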