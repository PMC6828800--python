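"""End-to-end scenario sweeps over the prioritization grid.

A ScenarioGrid crosses guilds x occupancy thresholds x relative-CV levels
x selection methods x replicate seeds. For each replicate one landscape
is generated, aggregated, and rescaled per (guild, threshold, cv) cell;
all three methods then run on the same rescaled table so the efficiency
comparisons are paired. Results land in a tidy CSV (one row per scenario
x target), a gains CSV, and a provenance JSON; failures are recorded as
rows and never abort the sweep.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import PlanningUnitTable, aggregate
from .cv_scaling import apply_relative_cv, coefficient_of_variation
from .efficiency import (
    TARGET_LADDER,
    AucOrientation,
    build_curve,
    compare_curves,
)
from .errors import ConfigError, ConsplanError
from .landscape import (
    GUILDS,
    FineLandscape,
    LandscapeConfig,
    generate_landscape,
)
from .prioritize import DEFAULT_GAP, Denominator, cost_correlation

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.25, 0.50, 0.75)
DEFAULT_CV_LEVELS = (2.0, 4.0, 8.0, 16.0)
DEFAULT_METHODS = ("min_cost", "min_area", "crank")


@dataclass(frozen=True)
class ScenarioGrid:
    """The full cross of experimental conditions."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    guilds: tuple[str, ...] = GUILDS
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    cv_relative_levels: tuple[float, ...] = DEFAULT_CV_LEVELS
    methods: tuple[str, ...] = DEFAULT_METHODS
    seeds: tuple[int, ...] = (1,)
    gap: float = DEFAULT_GAP
    denominator: Denominator = "post_threshold"
    auc_orientation: AucOrientation = "target_vs_cost"
    targets: tuple[float, ...] = TARGET_LADDER
    solver_time_limit: float | None = 60.0  # per-solve cap, seconds

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ConfigError("seeds list must be non-empty")
        if not self.guilds or not self.thresholds \
                or not self.cv_relative_levels or not self.methods:
            raise ConfigError("every grid axis must be non-empty")
        for g in self.guilds:
            if g not in GUILDS:
                raise ConfigError(f"unknown guild {g!r}")

    def scenario_keys(self):
        """Deterministic enumeration order of (seed, guild, threshold, cv)."""
        for seed in self.seeds:
            for guild in self.guilds:
                for thr in self.thresholds:
                    for cv in self.cv_relative_levels:
                        yield seed, guild, thr, cv

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["landscape"]["species_cv_range"] = list(
            d["landscape"]["species_cv_range"])
        for k in ("guilds", "thresholds", "cv_relative_levels", "methods",
                  "seeds", "targets"):
            d[k] = list(d[k])
        return d


def run_experiment(grid: ScenarioGrid,
                   output_dir: str | Path | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the sweep; return (solutions table, gains table).

    When ``output_dir`` is given, writes results.csv, gains.csv, and
    provenance.json there. Deterministic in the grid: landscapes are pure
    functions of their replicate seed, C-rank output is byte-stable, and
    MILP objectives agree within the solver gap across reruns.
    """
    rows: list[dict] = []
    gain_rows: list[dict] = []
    landscapes: dict[int, PlanningUnitTable] = {}
    for seed, guild, thr, cv in grid.scenario_keys():
        key = dict(seed=seed, guild=guild, threshold=thr, cv_relative=cv)
        logger.info("scenario %s", key)
        try:
            if seed not in landscapes:
                landscapes[seed] = aggregate(generate_landscape(
                    replace(grid.landscape, seed=seed)))
            units, cvspec = apply_relative_cv(
                landscapes[seed], cv,
                species_subset=landscapes[seed].guild_species(guild))
            curves = {
                m: build_curve(units, guild, thr, m, gap=grid.gap,
                               targets=grid.targets,
                               denominator=grid.denominator,
                               cv_relative=cv,
                               time_limit=grid.solver_time_limit)
                for m in grid.methods
            }
            for m, curve in curves.items():
                for rec in curve.to_records():
                    rows.append({**key, "method": m, **{
                        k: v for k, v in rec.items()
                        if k not in ("guild", "threshold", "cv_relative",
                                     "method")},
                        "status": "ok"})
            eff = compare_curves(curves, grid.auc_orientation)
            gain_rows.append({**key, **{f"auc_{m}": v
                                        for m, v in eff.auc.items()},
                              **eff.comparisons,
                              "delta_cost": cvspec.delta_cost,
                              "cv_benefit": cvspec.cv_benefit})
        except ConsplanError as exc:
            logger.warning("scenario %s failed: %s", key, exc)
            rows.append({**key, "method": None, "target": None,
                         "cost_fraction": None, "monetary_cost": None,
                         "feasible": None, "total_cost": None,
                         "status": f"failed: {exc}"})
    results = pd.DataFrame(rows)
    gains = pd.DataFrame(gain_rows)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        gains.to_csv(out / "gains.csv", index=False)
        provenance = {"grid": grid.to_dict(),
                      "package_version": __version__,
                      "numpy_version": np.__version__}
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2))
    return results, gains


def validate_landscape_report(landscape: FineLandscape) -> pd.DataFrame:
    """Calibration diagnostics mirroring the headline layer statistics:
    cost CV, cost range (orders of magnitude), per-species CVs and
    cost correlations, and guild means. Statistics are at fine (1-ha)
    resolution, the scale the generator calibrates."""
    rows = [{
        "kind": "cost", "id": "cost", "guild": None,
        "cv": (coefficient_of_variation(landscape.cost_fine.ravel())
               if landscape.cost_fine.std() > 0 else 0.0),
        "r_cost": None,
        "range_orders_of_magnitude": float(
            np.log10(landscape.cost_fine.max() / landscape.cost_fine.min())),
    }]
    if landscape.cost_fine.std() == 0:
        logger.warning("degenerate constant cost layer: CV = 0")
    flat_cost = landscape.cost_fine.ravel()
    r_by_guild: dict[str, list[float]] = {g: [] for g in GUILDS}
    for i, (sid, g) in enumerate(zip(landscape.species_ids,
                                     landscape.guilds)):
        occ = landscape.occupancy_fine[i].ravel()
        r = float(np.corrcoef(occ, flat_cost)[0, 1])
        r_by_guild[g].append(r)
        rows.append({"kind": "species", "id": sid, "guild": g,
                     "cv": coefficient_of_variation(occ), "r_cost": r,
                     "range_orders_of_magnitude": None})
    for g, rs in r_by_guild.items():
        if rs:
            rows.append({"kind": "guild_mean", "id": g, "guild": g,
                         "cv": None, "r_cost": float(np.mean(rs)),
                         "range_orders_of_magnitude": None})
    return pd.DataFrame(rows)
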