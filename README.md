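# consplan

When does better biodiversity data — or better land-cost data — actually
improve a spatial conservation plan? `consplan` is a Python toolkit for
studying that question with controlled experiments: it generates
synthetic landscapes whose cost and species-occupancy layers have
prescribed statistical structure, selects reserve networks with an exact
integer-programming solver and simple baselines, and compares the
efficiency of plans built with and without each kind of data.

It is aimed at conservation scientists and methods developers who want a
reproducible, seeded sandbox for reserve-selection experiments rather
than a one-off GIS workflow.

## The model

The core selection problem is the **minimum set problem**: choose planning
units `x_i ∈ {0, 1}` to

    minimize    Σ_i w_i x_i
    subject to  Σ_i p_si x_i ≥ T_s        for every species s

where `w_i` is the unit's cost (or 1 for the minimum-area variant),
`p_si` is the species' mean occupancy probability in unit *i* (zeroed
below a suitability threshold of 25/50/75%), and `T_s` is a target
fraction (5–100%) of the species' total occupancy over suitable units.
The ILP is solved with HiGHS branch-and-bound to a 1% optimality gap by
default. Two baselines bracket the value of data: **C-rank** buys units
cheapest-first until targets are met (no biodiversity information enters
the ordering), and **min-area** ignores cost (all `w_i = 1`).

The relative variability of benefits versus costs is manipulated by
adding a constant to every unit cost,

    Δ_cost = CV_relative · SD_cost / CV_benefit − μ_cost,

which lowers the cost CV without changing its SD, so that
`CV_benefit / CV_cost` hits a requested level (2, 4, 8, or 16). Plans are
compared by the area under their cost-benefit curves (achieved target vs
fraction of total landscape cost; higher AUC = more efficient), and by
fractional gains `(AUC_with − AUC_without) / AUC_without` between
scenarios that include or exclude cost or biodiversity data.

Synthetic landscapes are calibrated to realistic summary statistics by
deterministic root searches on the realized grids: a heavy-tailed cost
layer with sample CV 7.25, twenty species occupancy layers with CVs
spanning 0.407–1.415, and two guilds whose occupancy is weakly positively
("human-associated", r ≈ +0.08) or negatively ("forest", r ≈ −0.07)
correlated with land cost. See `docs/methods.md` for the full model and
its limitations.

## Worked example

```python
import numpy as np
from consplan import *

config = LandscapeConfig(n_rows_fine=100, n_cols_fine=100, seed=42)
landscape = generate_landscape(config)
units = aggregate(landscape)                      # 100 planning units

print(f"cost CV: {coefficient_of_variation(landscape.cost_fine.ravel()):.2f}")
r = np.mean([cost_correlation(units, s) for s in units.guild_species("human")])
print(f"human-guild mean cost correlation: {r:+.3f}")

# flatten the cost layer so benefits are 8x as variable as costs
rescaled, spec = apply_relative_cv(units, 8.0,
                                   species_subset=units.guild_species("human"))
print(f"delta_cost: {spec.delta_cost:.4g}")

curves = {m: build_curve(rescaled, "human", 0.75, m, time_limit=30)
          for m in ("min_cost", "min_area", "crank")}
eff = compare_curves(curves)
for name, auc in eff.auc.items():
    print(f"AUC[{name}] = {auc:.3f}")
for name, gain in eff.comparisons.items():
    print(f"{name} = {gain:+.3f}")
```

Output:

```
cost CV: 7.25
human-guild mean cost correlation: +0.120
delta_cost: 3.676e+09
AUC[min_cost] = 0.621
AUC[min_area] = 0.615
AUC[crank] = 0.148
gain_cost_data = +0.009
gain_biodiversity_data = +3.202
```

Read: on this landscape the generator hit its cost-variability target
exactly and the human-associated guild sits on expensive land. After
flattening the costs (relative CV 8), adding cost data to a
biodiversity-driven plan is nearly worthless (+0.9% efficiency), while
adding biodiversity data to a cost-only plan quadruples efficiency —
cheap land tells you almost nothing once costs are homogeneous.

A command-line interface mirrors the library
(`consplan generate | aggregate | rescale | solve | curve | sweep |
report`); `consplan sweep --config grid.yaml --output out/` runs the full
scenario cross and writes tidy CSVs plus a provenance JSON.

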