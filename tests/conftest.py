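"""Shared fixtures: seeded landscapes and small hand-built unit tables."""

import numpy as np
import pytest

from consplan import (
    LandscapeConfig,
    PlanningUnitTable,
    aggregate,
    generate_landscape,
)


@pytest.fixture(scope="session")
def default_landscape():
    """Full-size landscape at the default configuration (400 units)."""
    return generate_landscape(LandscapeConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale configuration: 100x100 fine cells -> 100 units."""
    return LandscapeConfig(n_rows_fine=100, n_cols_fine=100, seed=1)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_units(small_landscape):
    return aggregate(small_landscape)


def make_table(costs, occupancy, species_ids=None):
    """Hand-built planning-unit table; occupancy is (n_species, n_units)."""
    costs = np.asarray(costs, dtype=float)
    occupancy = np.atleast_2d(np.asarray(occupancy, dtype=float))
    n_species = occupancy.shape[0]
    if species_ids is None:
        species_ids = tuple(f"forest_{i + 1:02d}" for i in range(n_species))
    guilds = tuple(s.split("_")[0] for s in species_ids)
    n = len(costs)
    return PlanningUnitTable(
        cost=costs, occupancy=occupancy,
        row=np.zeros(n, dtype=int), col=np.arange(n),
        species_ids=tuple(species_ids), guilds=guilds,
    )


def random_table(seed, n_units=None, n_species=None):
    """Random small instance: positive costs, uniform occupancies."""
    rng = np.random.default_rng(seed)
    if n_units is None:
        n_units = int(rng.integers(10, 13))
    if n_species is None:
        n_species = int(rng.integers(2, 4))
    costs = rng.uniform(1.0, 100.0, n_units)
    occ = rng.uniform(0.0, 1.0, (n_species, n_units))
    return make_table(costs, occ)
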