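"""Aggregation of fine cells into planning units.

Planning units are axis-aligned ``factor x factor`` blocks of fine cells,
anchored at the grid origin, laid out row-major with 0-based ids. Cost is
summed over the block (total acquisition cost of the unit); occupancy is
averaged (mean probability of occurrence across the unit). Partial edge
blocks are an error: mixing unit areas would distort the unit-count
(minimum-area) objective.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import AggregationError, GuildError, SpeciesError
from .landscape import GUILDS, FineLandscape


@dataclass(frozen=True)
class PlanningUnitTable:
    """Per-unit cost and per-species mean occupancy after aggregation."""

    cost: np.ndarray          # (n_units,)
    occupancy: np.ndarray     # (n_species, n_units)
    row: np.ndarray           # (n_units,) unit-grid row
    col: np.ndarray           # (n_units,) unit-grid col
    species_ids: tuple[str, ...]
    guilds: tuple[str, ...]

    def __post_init__(self) -> None:
        n = self.cost.shape[0]
        if self.occupancy.shape != (len(self.species_ids), n):
            raise AggregationError("occupancy shape mismatch")
        if len(self.guilds) != len(self.species_ids):
            raise AggregationError("one guild label per species required")
        if self.row.shape != (n,) or self.col.shape != (n,):
            raise AggregationError("row/col shape mismatch")

    @property
    def n_units(self) -> int:
        return int(self.cost.shape[0])

    @property
    def unit_ids(self) -> np.ndarray:
        return np.arange(self.n_units)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def species_index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise SpeciesError(f"unknown species {species_id!r}") from None

    def guild_species(self, guild: str) -> tuple[str, ...]:
        if guild not in GUILDS:
            raise GuildError(f"unknown guild {guild!r}; expected one of {GUILDS}")
        return tuple(s for s, g in zip(self.species_ids, self.guilds)
                     if g == guild)

    def with_costs(self, new_cost: np.ndarray) -> "PlanningUnitTable":
        """Same table with a replaced cost vector (occupancy untouched)."""
        new_cost = np.asarray(new_cost, dtype=float)
        if new_cost.shape != self.cost.shape:
            raise AggregationError("cost vector shape mismatch")
        return replace(self, cost=new_cost)

    # --- CSV interface: unit_id,row,col,cost, then one column per species ---

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "unit_id": self.unit_ids,
            "row": self.row,
            "col": self.col,
            "cost": self.cost,
        })
        for i, sid in enumerate(self.species_ids):
            df[sid] = self.occupancy[i]
        return df

    def to_csv(self, path_or_buf) -> None:
        self.to_dataframe().to_csv(path_or_buf, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PlanningUnitTable":
        meta = ["unit_id", "row", "col", "cost"]
        species = [c for c in df.columns if c not in meta]
        guilds = []
        for sid in species:
            guild = sid.split("_")[0]
            if guild not in GUILDS:
                raise GuildError(
                    f"cannot infer guild from species column {sid!r}")
            guilds.append(guild)
        df = df.sort_values("unit_id")
        if not np.array_equal(df["unit_id"].to_numpy(),
                              np.arange(len(df))):
            raise AggregationError("unit_id must be a bijection onto 0..n-1")
        return cls(cost=df["cost"].to_numpy(dtype=float),
                   occupancy=df[species].to_numpy(dtype=float).T,
                   row=df["row"].to_numpy(dtype=int),
                   col=df["col"].to_numpy(dtype=int),
                   species_ids=tuple(species), guilds=tuple(guilds))

    @classmethod
    def from_csv(cls, path_or_buf) -> "PlanningUnitTable":
        return cls.from_dataframe(pd.read_csv(path_or_buf))


def _blocks(grid: np.ndarray, factor: int) -> np.ndarray:
    """Reshape (R, C) into (R/f, C/f, f*f) blocks."""
    r, c = grid.shape
    return (grid.reshape(r // factor, factor, c // factor, factor)
            .transpose(0, 2, 1, 3)
            .reshape(r // factor, c // factor, factor * factor))


def _check_divisible(landscape: FineLandscape, factor: int) -> None:
    if factor < 1:
        raise AggregationError("aggregation factor must be >= 1")
    r, c = landscape.cost_fine.shape
    if r % factor or c % factor:
        raise AggregationError(
            f"fine grid {r}x{c} not divisible by factor {factor}; "
            "partial edge units are not allowed")


def aggregate(landscape: FineLandscape,
              factor: int | None = None) -> PlanningUnitTable:
    """Collapse fine cells into planning units: cost summed, occupancy
    averaged over each ``factor x factor`` block.

    ``factor`` defaults to the landscape config's aggregation_factor.
    """
    if factor is None:
        factor = landscape.config.aggregation_factor
    _check_divisible(landscape, factor)
    cost_u = _blocks(landscape.cost_fine, factor).sum(axis=2)
    occ_u = np.stack([_blocks(layer, factor).mean(axis=2)
                      for layer in landscape.occupancy_fine])
    nr, nc = cost_u.shape
    rows, cols = np.divmod(np.arange(nr * nc), nc)
    return PlanningUnitTable(cost=cost_u.ravel(),
                             occupancy=occ_u.reshape(len(landscape.species_ids), -1),
                             row=rows, col=cols,
                             species_ids=landscape.species_ids,
                             guilds=landscape.guilds)


def coarsen(landscape: FineLandscape, factor: int) -> FineLandscape:
    """Return a coarser FineLandscape (cost summed, occupancy averaged),
    useful for multi-stage aggregation; aggregate(coarsen(x, a), b) equals
    aggregate(x, a*b)."""
    _check_divisible(landscape, factor)
    cost = _blocks(landscape.cost_fine, factor).sum(axis=2)
    occ = np.stack([_blocks(layer, factor).mean(axis=2)
                    for layer in landscape.occupancy_fine])
    cfg = replace(landscape.config,
                  n_rows_fine=cost.shape[0], n_cols_fine=cost.shape[1],
                  aggregation_factor=1)
    return FineLandscape(cost_fine=cost, occupancy_fine=occ,
                         species_ids=landscape.species_ids,
                         guilds=landscape.guilds, config=cfg)
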