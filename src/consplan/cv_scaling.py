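"""Relative-CV manipulation of the cost layer.

The influence of cost data on a prioritization depends on how variable
costs are relative to the biodiversity benefit layers. That relative
variability is manipulated by adding a single fixed offset to every unit
cost: the shift raises the mean without touching the standard deviation,
so it lowers the cost CV while preserving the cost ordering of units.

The offset that makes CV_benefit / CV_cost equal a requested level is

    delta = cv_relative * sd_cost / cv_benefit - mu_cost

where cv_benefit is the average of the per-species occupancy-layer CVs
(held constant throughout) and CV = SD / mean with the sample SD (ddof=1)
convention used package-wide.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .aggregation import PlanningUnitTable
from .errors import (
    ConfigError,
    DegenerateInputError,
    NegativeCostError,
    SubsetError,
    UndefinedCVError,
)


@dataclass(frozen=True)
class CVScalingSpec:
    """Provenance record of one relative-CV rescaling."""

    cv_relative: float
    mu_cost: float
    sd_cost: float
    cv_benefit: float
    delta_cost: float

    def to_dict(self) -> dict:
        return asdict(self)


def coefficient_of_variation(values: Sequence[float] | np.ndarray) -> float:
    """Sample CV: SD (ddof=1) divided by the mean.

    Scale-invariant under positive scaling; undefined for zero mean or
    fewer than two values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DegenerateInputError("CV needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise UndefinedCVError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


def benefit_cv(units: PlanningUnitTable,
               species_subset: Sequence[str]) -> float:
    """Average of per-species occupancy CVs over the subset, computed at
    planning-unit resolution (the scale the optimizer operates at)."""
    if len(species_subset) == 0:
        raise SubsetError("species subset must be non-empty")
    cvs = [coefficient_of_variation(units.occupancy[units.species_index(s)])
           for s in species_subset]
    return float(np.mean(cvs))


def compute_delta_cost(mu_cost: float, sd_cost: float, cv_benefit: float,
                       cv_relative: float) -> float:
    """Additive cost offset achieving the requested relative CV."""
    if sd_cost <= 0:
        raise ConfigError("sd_cost must be > 0")
    if cv_benefit <= 0:
        raise ConfigError("cv_benefit must be > 0")
    if cv_relative <= 0:
        raise ConfigError("cv_relative must be > 0")
    return cv_relative * sd_cost / cv_benefit - mu_cost


def apply_relative_cv(units: PlanningUnitTable, cv_relative: float,
                      species_subset: Sequence[str] | None = None,
                      ) -> tuple[PlanningUnitTable, CVScalingSpec]:
    """Shift all unit costs by the delta that makes
    CV_benefit / CV_cost == cv_relative.

    ``species_subset`` selects the layers entering the benefit CV (default
    all species). Occupancy columns are untouched and the cost SD is
    exactly preserved. Raises NegativeCostError when the requested ratio
    is below the raw ratio by enough that the shift would drive some unit
    cost to zero or below.
    """
    if species_subset is None:
        species_subset = units.species_ids
    cvb = benefit_cv(units, species_subset)
    mu = float(units.cost.mean())
    sd = float(units.cost.std(ddof=1))
    delta = compute_delta_cost(mu, sd, cvb, cv_relative)
    new_cost = units.cost + delta
    min_cost = float(new_cost.min())
    if min_cost <= 0:
        raise NegativeCostError(delta, min_cost)
    spec = CVScalingSpec(cv_relative=float(cv_relative), mu_cost=mu,
                         sd_cost=sd, cv_benefit=cvb, delta_cost=delta)
    return units.with_costs(new_cost), spec
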