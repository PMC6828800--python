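"""Synthetic-landscape generator: determinism, calibration, invariants."""

import numpy as np
import pytest

from consplan import (
    GUILDS,
    LandscapeConfig,
    aggregate,
    coefficient_of_variation,
    generate_cost_layer,
    generate_field,
    generate_landscape,
    generate_species_layer,
    neighbor_correlation,
)
from consplan.errors import (
    ConfigError,
    DegenerateInputError,
    DimensionError,
    GuildError,
)


class TestGenerateField:
    def test_standardized_and_deterministic(self):
        f1 = generate_field(50, 50, 0.0, seed=1)
        f2 = generate_field(50, 50, 0.0, seed=1)
        assert np.array_equal(f1, f2)
        assert abs(f1.mean()) < 1e-9
        assert abs(f1.std(ddof=1) - 1.0) < 1e-9
        assert not np.array_equal(f1, generate_field(50, 50, 0.0, seed=2))

    def test_single_cell_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            generate_field(1, 1, 0.0, seed=1)

    @pytest.mark.parametrize("shape", [(0, 5), (5, 0), (-1, 3)])
    def test_nonpositive_dimensions_rejected(self, shape):
        with pytest.raises(DimensionError):
            generate_field(*shape, 0.0, seed=1)

    def test_smoothing_raises_spatial_autocorrelation(self):
        # independent oracle: lag-1 neighbor correlation measured directly
        white = generate_field(50, 50, 0.0, seed=1)
        smooth = generate_field(50, 50, 5.0, seed=1)
        assert neighbor_correlation(smooth) > neighbor_correlation(white)
        assert neighbor_correlation(smooth) > 0.5


class TestCostLayer:
    def test_sample_cv_matches_target(self):
        cfg = LandscapeConfig(seed=1)
        field = generate_field(200, 200, cfg.smoothing_length, seed=1)
        cost = generate_cost_layer(cfg, field)
        assert 6.5 <= coefficient_of_variation(cost.ravel()) <= 8.0

    def test_positive_and_heavy_tailed(self):
        cfg = LandscapeConfig(seed=1)
        field = generate_field(200, 200, cfg.smoothing_length, seed=1)
        cost = generate_cost_layer(cfg, field)
        assert cost.min() > 0
        assert cost.max() / cost.min() >= 1e3

    def test_zero_spread_gives_constant_layer(self):
        cfg = LandscapeConfig(cost_log_spread=0.0, seed=1)
        field = generate_field(100, 100, 0.0, seed=1)
        cost = generate_cost_layer(cfg, field)
        assert np.all(cost == cost.flat[0])

    def test_nonpositive_cv_target_rejected(self):
        with pytest.raises(ConfigError):
            LandscapeConfig(cost_cv_target=0.0)


@pytest.fixture(scope="module")
def shared_field():
    return generate_field(200, 200, 6.0, seed=11)


class TestSpeciesLayer:
    def test_zero_loading_uncorrelated(self, shared_field):
        cfg = LandscapeConfig(seed=11)
        layer = generate_species_layer(cfg, shared_field, "human", seed=5,
                                       cost_loading=0.0)
        r = np.corrcoef(layer.ravel(), shared_field.ravel())[0, 1]
        assert abs(r) < 0.05

    @pytest.mark.parametrize("guild,sign", [("human", 1), ("forest", -1)])
    def test_guild_correlation_sign(self, shared_field, guild, sign):
        cfg = LandscapeConfig(seed=11)
        cost = generate_cost_layer(cfg, shared_field)
        layer = generate_species_layer(cfg, shared_field, guild, seed=5,
                                       cost_grid=cost)
        r = np.corrcoef(layer.ravel(), cost.ravel())[0, 1]
        assert np.sign(r) == sign

    def test_unknown_guild_rejected(self, shared_field):
        with pytest.raises(GuildError):
            generate_species_layer(LandscapeConfig(), shared_field,
                                   "wetland", seed=0)


class TestGenerateLandscape:
    def test_deterministic(self, small_config, small_landscape):
        again = generate_landscape(small_config)
        assert np.array_equal(again.cost_fine, small_landscape.cost_fine)
        assert np.array_equal(again.occupancy_fine,
                              small_landscape.occupancy_fine)

    def test_species_counts_and_order(self, small_landscape):
        assert small_landscape.n_species == 20
        assert small_landscape.guilds[:10] == ("forest",) * 10
        assert small_landscape.guilds[10:] == ("human",) * 10
        tiny = generate_landscape(LandscapeConfig(
            n_rows_fine=60, n_cols_fine=60, n_species_per_guild=1, seed=2))
        assert tiny.n_species == 2

    def test_occupancy_bounded_and_finite(self, small_landscape):
        occ = small_landscape.occupancy_fine
        assert np.all((occ >= 0) & (occ <= 1))
        assert np.all(np.isfinite(occ))
        assert np.all(np.isfinite(small_landscape.cost_fine))

    def test_species_cvs_span_configured_range(self, small_landscape):
        lo, hi = small_landscape.config.species_cv_range
        cvs = [coefficient_of_variation(layer.ravel())
               for layer in small_landscape.occupancy_fine]
        assert min(cvs) == pytest.approx(lo, rel=0.25)
        assert max(cvs) == pytest.approx(hi, rel=0.25)
        assert all(0.3 < c < 1.8 for c in cvs)

    def test_calibration_recovery_across_seeds(self):
        """Cost CV and guild correlation signs recover over many seeds."""
        cost_cvs, sign_ok = [], []
        for seed in range(1, 21):
            ls = generate_landscape(LandscapeConfig(
                n_rows_fine=100, n_cols_fine=100, seed=seed))
            cost_cvs.append(coefficient_of_variation(ls.cost_fine.ravel()))
            flat_cost = ls.cost_fine.ravel()
            means = {}
            for g in GUILDS:
                idx = [i for i, gg in enumerate(ls.guilds) if gg == g]
                means[g] = np.mean([
                    np.corrcoef(ls.occupancy_fine[i].ravel(), flat_cost)[0, 1]
                    for i in idx])
            sign_ok.append(means["human"] > 0 > means["forest"])
        target = LandscapeConfig().cost_cv_target
        assert np.mean(cost_cvs) == pytest.approx(target, rel=0.15)
        assert all(sign_ok)
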