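"""Synthetic fine-resolution landscapes for prioritization experiments.

Real applications of this package start from a land-cost raster and
per-species occupancy-probability rasters. Because such layers (cadastral
assessed values, occupancy-model predictions) are rarely redistributable,
this module generates seeded stand-ins with the same statistical structure:

* a heavy-tailed cost layer spanning several orders of magnitude with a
  very high coefficient of variation (default target CV = 7.25),
* two guilds of species occupancy layers in [0, 1] — "human"-associated
  species weakly positively correlated with land cost and "forest" species
  weakly negatively correlated (default targets r = +0.083 and -0.066),
* per-species occupancy CVs spanning a configurable range (default
  0.407-1.415),
* 1-ha fine cells aggregable into 1-km^2 planning units (factor 10).

Construction: a shared latent Gaussian random field drives the cost layer
(log-linear transform) and, with a per-guild loading, each species layer
(inverse-logit of a linear combination with an independent field). The
loading and the logistic intercept are calibrated per species by a
deterministic root search so the sampled correlation and CV hit their
targets on the realized grid, making the generator a pure function of its
configuration (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import pearsonr

from .errors import (
    CalibrationError,
    ConfigError,
    DegenerateInputError,
    DimensionError,
    GuildError,
)

GUILDS = ("forest", "human")
Guild = Literal["forest", "human"]

# latent-field loading of the species-independent component; large enough
# that high-occupancy pockets exist even after 10x10 aggregation, so 0.75
# occupancy thresholds leave eligible planning units
_SPECIES_FIELD_LOADING = 3.0


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of a synthetic landscape.

    Defaults reproduce the study conditions this generator emulates:
    a 200x200 grid of 1-ha cells aggregating by 10 into 400 planning
    units, 10 species per guild, cost CV 7.25, species CVs spanning
    0.407-1.415, and guild-level cost correlations +0.083 / -0.066.
    ``smoothing_length`` (in fine cells) sets the spatial autocorrelation
    scale of every latent field; it has no empirical anchor and exists for
    realism — 6 cells (600 m) is of the order of habitat-patch structure.
    ``cost_mean_fine`` only fixes the monetary scale (mean cost per fine
    cell); every downstream statistic is scale-free.
    """

    n_rows_fine: int = 200
    n_cols_fine: int = 200
    aggregation_factor: int = 10
    n_species_per_guild: int = 10
    cost_cv_target: float = 7.25
    cost_log_spread: float = 2.0
    species_cv_range: tuple[float, float] = (0.407, 1.415)
    corr_target_human: float = 0.083
    corr_target_forest: float = -0.066
    smoothing_length: float = 6.0
    cost_mean_fine: float = 7.8e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows_fine < 1 or self.n_cols_fine < 1:
            raise DimensionError("grid dimensions must be >= 1")
        if self.aggregation_factor < 1:
            raise ConfigError("aggregation_factor must be >= 1")
        if (self.n_rows_fine % self.aggregation_factor
                or self.n_cols_fine % self.aggregation_factor):
            raise ConfigError(
                "n_rows_fine and n_cols_fine must be divisible by "
                "aggregation_factor"
            )
        if self.n_species_per_guild < 1:
            raise ConfigError("n_species_per_guild must be >= 1")
        if self.cost_cv_target <= 0:
            raise ConfigError("cost_cv_target must be > 0")
        if self.cost_log_spread < 0:
            raise ConfigError("cost_log_spread must be >= 0")
        lo, hi = self.species_cv_range
        if not (0 < lo <= hi):
            raise ConfigError("species_cv_range must satisfy 0 < low <= high")
        for r in (self.corr_target_human, self.corr_target_forest):
            if not -1 < r < 1:
                raise ConfigError("correlation targets must lie in (-1, 1)")
        if self.smoothing_length < 0:
            raise ConfigError("smoothing_length must be >= 0")
        if self.cost_mean_fine <= 0:
            raise ConfigError("cost_mean_fine must be > 0")

    def corr_target(self, guild: str) -> float:
        if guild == "human":
            return self.corr_target_human
        if guild == "forest":
            return self.corr_target_forest
        raise GuildError(f"unknown guild {guild!r}; expected one of {GUILDS}")


@dataclass(frozen=True)
class FineLandscape:
    """Fine-resolution cost grid plus per-species occupancy grids."""

    cost_fine: np.ndarray               # (rows, cols), strictly positive
    occupancy_fine: np.ndarray          # (n_species, rows, cols), in [0, 1]
    species_ids: tuple[str, ...]
    guilds: tuple[str, ...]             # per-species guild label
    config: LandscapeConfig

    def __post_init__(self) -> None:
        if self.cost_fine.ndim != 2:
            raise DimensionError("cost_fine must be 2-D")
        if self.occupancy_fine.shape != (
                len(self.species_ids),) + self.cost_fine.shape:
            raise DimensionError("occupancy_fine shape mismatch")
        if len(self.guilds) != len(self.species_ids):
            raise ConfigError("one guild label per species required")
        if not np.all(np.isfinite(self.cost_fine)) or np.any(self.cost_fine <= 0):
            raise ConfigError("costs must be strictly positive and finite")
        if (np.any(self.occupancy_fine < 0) or np.any(self.occupancy_fine > 1)
                or not np.all(np.isfinite(self.occupancy_fine))):
            raise ConfigError("occupancy must lie in [0, 1]")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def species_index(self, species_id: str) -> int:
        try:
            return self.species_ids.index(species_id)
        except ValueError:
            raise GuildError(f"unknown species {species_id!r}") from None

    def guild_species(self, guild: str) -> tuple[str, ...]:
        if guild not in GUILDS:
            raise GuildError(f"unknown guild {guild!r}; expected one of {GUILDS}")
        return tuple(s for s, g in zip(self.species_ids, self.guilds)
                     if g == guild)


def _sample_cv(values: np.ndarray) -> float:
    # sample SD (ddof=1) over sample mean; the package-wide CV convention
    return float(np.std(values, ddof=1) / np.mean(values))


def _child_seed(seed: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(seed)] + [int(t) for t in tags])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_field(n_rows: int, n_cols: int, smoothing_length: float,
                   seed: int) -> np.ndarray:
    """Seeded Gaussian random field standardized to mean 0, sample SD 1.

    ``smoothing_length`` is the Gaussian-kernel sigma in cells; 0 gives
    white noise. Wrap-around boundary keeps the marginal variance uniform.
    """
    if n_rows < 1 or n_cols < 1:
        raise DimensionError("field dimensions must be >= 1")
    if n_rows * n_cols < 2:
        raise DegenerateInputError(
            "cannot standardize a single-cell field (sample SD undefined)")
    if smoothing_length < 0:
        raise ConfigError("smoothing_length must be >= 0")
    rng = np.random.default_rng(seed)
    grid = rng.standard_normal((n_rows, n_cols))
    if smoothing_length > 0:
        grid = gaussian_filter(grid, sigma=smoothing_length, mode="wrap")
    sd = grid.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("field has zero variance")
    return (grid - grid.mean()) / sd


def neighbor_correlation(grid: np.ndarray) -> float:
    """Average lag-1 Pearson correlation over horizontal and vertical
    neighbor pairs (a Moran-style spatial autocorrelation diagnostic)."""
    h = pearsonr(grid[:, :-1].ravel(), grid[:, 1:].ravel()).statistic
    v = pearsonr(grid[:-1, :].ravel(), grid[1:, :].ravel()).statistic
    return float((h + v) / 2.0)


def generate_cost_layer(config: LandscapeConfig,
                        field: np.ndarray) -> np.ndarray:
    """Heavy-tailed cost layer: a log-linear transform of the latent field.

    cost = scale * exp(s * field), with the effective log-spread ``s``
    solved on the realized field so the sample CV equals
    ``config.cost_cv_target`` (the printed-statistic calibration).
    ``cost_log_spread`` bounds the search; 0 short-circuits to a constant
    layer. The multiplicative scale sets the mean to ``cost_mean_fine``
    and leaves the CV untouched.
    """
    if config.cost_cv_target <= 0:
        raise ConfigError("cost_cv_target must be > 0")
    if config.cost_log_spread == 0:
        return np.full_like(field, config.cost_mean_fine, dtype=float)

    def cv_minus_target(s: float) -> float:
        return _sample_cv(np.exp(s * field)) - config.cost_cv_target

    s_max = 6.0 * config.cost_log_spread
    if cv_minus_target(s_max) < 0:
        raise CalibrationError(
            f"cost CV target {config.cost_cv_target} unreachable with "
            f"log-spread <= {s_max}; increase cost_log_spread")
    s = brentq(cv_minus_target, 1e-9, s_max, xtol=1e-12)
    cost = np.exp(s * field)
    return cost * (config.cost_mean_fine / cost.mean())


def _calibrate_species(config: LandscapeConfig, cost_field: np.ndarray,
                       z: np.ndarray, corr_ref: np.ndarray,
                       corr_target: float, cv_target: float) -> np.ndarray:
    """Solve (intercept, cost loading) so the realized occupancy layer has
    the requested sample CV and Pearson correlation with ``corr_ref``."""
    b = _SPECIES_FIELD_LOADING
    ref = corr_ref.ravel()

    def occupancy(a: float, c: float) -> np.ndarray:
        return expit(a * cost_field + b * z + c)

    a, c = 0.0, 0.0
    for _ in range(2):  # CV depends mostly on c, correlation on a
        def cv_err(ci: float, ai: float = a) -> float:
            return _sample_cv(occupancy(ai, ci)) - cv_target

        if cv_err(-14.0) < 0 or cv_err(14.0) > 0:
            raise CalibrationError(
                f"species CV target {cv_target} unreachable")
        c = brentq(cv_err, -14.0, 14.0, xtol=1e-10)

        def corr_err(ai: float, ci: float = c) -> float:
            r = pearsonr(occupancy(ai, ci).ravel(), ref).statistic
            return r - corr_target

        # heavy-tailed costs attenuate r, so small grids can need a large
        # loading; widen the bracket until the target is straddled
        for half_width in (2.0, 6.0, 12.0):
            if corr_err(-half_width) <= 0 <= corr_err(half_width):
                a = brentq(corr_err, -half_width, half_width, xtol=1e-10)
                break
        else:
            raise CalibrationError(
                f"correlation target {corr_target} unreachable")
    return occupancy(a, c)


def generate_species_layer(config: LandscapeConfig, cost_field: np.ndarray,
                           guild: str, seed: int, *,
                           cv_target: float | None = None,
                           cost_loading: float | None = None,
                           cost_grid: np.ndarray | None = None) -> np.ndarray:
    """One species occupancy layer, inverse-logit of a latent mixture.

    The layer is expit(a * cost_field + b * z + c) with ``z`` an
    independent seeded field. By default ``a`` and ``c`` are calibrated so
    the sampled correlation with ``cost_grid`` (the raw cost layer when
    supplied, else the latent ``cost_field``) equals the guild's target and
    the sample CV equals ``cv_target``. Passing ``cost_loading`` fixes
    ``a`` and skips correlation calibration (CV is still matched).
    """
    if guild not in GUILDS:
        raise GuildError(f"unknown guild {guild!r}; expected one of {GUILDS}")
    if cv_target is None:
        lo, hi = config.species_cv_range
        cv_target = 0.5 * (lo + hi)
    z = generate_field(cost_field.shape[0], cost_field.shape[1],
                       config.smoothing_length, seed)
    ref = cost_grid if cost_grid is not None else cost_field
    if np.std(ref) == 0:  # constant cost layer: correlate against the latent
        ref = cost_field
    if cost_loading is not None:
        b = _SPECIES_FIELD_LOADING

        def cv_err(ci: float) -> float:
            occ = expit(cost_loading * cost_field + b * z + ci)
            return _sample_cv(occ) - cv_target

        c = brentq(cv_err, -14.0, 14.0, xtol=1e-10)
        return expit(cost_loading * cost_field + b * z + c)
    return _calibrate_species(config, cost_field, z, ref,
                              config.corr_target(guild), cv_target)


def generate_landscape(config: LandscapeConfig) -> FineLandscape:
    """Assemble the full landscape: cost plus both guilds of species.

    Species are ordered forest guild first, then human, each in generation
    order; per-species CV targets are evenly spaced over
    ``species_cv_range`` so the realized layers span the configured range.
    Fully deterministic in ``config`` (per-species seeds derive from
    ``config.seed`` via a seed sequence).
    """
    shared = generate_field(config.n_rows_fine, config.n_cols_fine,
                            config.smoothing_length,
                            _child_seed(config.seed, 0))
    cost = generate_cost_layer(config, shared)
    n = config.n_species_per_guild
    lo, hi = config.species_cv_range
    cv_targets = (np.linspace(lo, hi, n) if n > 1
                  else np.array([(lo + hi) / 2.0]))
    layers, ids, guilds = [], [], []
    for gi, guild in enumerate(GUILDS):  # forest first, then human
        for i in range(n):
            layer = generate_species_layer(
                config, shared, guild,
                _child_seed(config.seed, gi + 1, i),
                cv_target=float(cv_targets[i]), cost_grid=cost)
            layers.append(layer)
            ids.append(f"{guild}_{i + 1:02d}")
            guilds.append(guild)
    return FineLandscape(cost_fine=cost,
                         occupancy_fine=np.stack(layers),
                         species_ids=tuple(ids),
                         guilds=tuple(guilds),
                         config=config)
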