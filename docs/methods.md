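# Methods

## Problem

Systematic conservation planning selects a portfolio of planning units
that meets representation targets for a set of biodiversity features at
minimum cost (the *minimum set problem*). Whether acquiring better
biodiversity data or better land-cost data improves such plans depends on
the relative spatial variability of the two kinds of layers and on how
they are correlated. `consplan` implements the machinery to study this
question on controlled synthetic landscapes: layer generation,
aggregation to planning units, a relative-variability manipulation of the
cost layer, exact and baseline selection algorithms, and an AUC-based
efficiency comparison.

## Synthetic landscapes

Real inputs of this kind (occupancy-model predictions, cadastral assessed
land values) are rarely redistributable, so the generator is a
first-class part of the package. It builds, on a fine grid of 1-ha cells:

* **A latent Gaussian random field** `f`: white noise smoothed with a
  Gaussian kernel (`smoothing_length` cells, wrap-around boundary) and
  standardized to sample mean 0 / SD 1. Smoothing exists for realism
  only — no selection stage uses adjacency (no boundary-length penalty) —
  and has no empirical anchor; the default of 6 cells (600 m) is of the
  order of habitat-patch structure in mixed-use landscapes.
* **The cost layer** `cost = s0 * exp(s * f)`: lognormal-type, strictly
  positive, heavy-tailed. The effective log-spread `s` is solved by a
  bracketed root search *on the realized field* so the sample CV equals
  `cost_cv_target` (default 7.25) exactly; the multiplicative scale `s0`
  sets the mean (default $780k per ha-cell, i.e. ~$78M per km² unit) and
  does not affect any scale-free statistic. The default layers span
  roughly five orders of magnitude between the cheapest and most
  expensive cell.
* **Species occupancy layers** `expit(a*f + b*z + c)`, one per species,
  with `z` an independent smoothed field per species and `b = 3`. For
  each species the intercept `c` is solved so the layer's sample CV hits
  a per-species target (targets evenly spaced over `species_cv_range`,
  default 0.407–1.415, so the realized layers span the configured range),
  and the cost loading `a` is solved so the Pearson correlation with the
  raw cost layer equals the guild target (+0.083 for human-associated
  species, −0.066 for forest species). The two one-dimensional solves
  alternate twice; the coupling between them is weak (|a| ≪ b).

All randomness derives from the config seed through `SeedSequence`
hashing; the generator is a pure function of its configuration.

Design notes and deliberate gaps:

* Every species in a guild is calibrated to the *same* correlation
  target, so the generator reproduces the guild means but not the
  across-species spread of cost correlations found in real communities.
* The latent loading `b = 3` is chosen so that saturated high-occupancy
  pockets survive 10×10 block averaging: a 75% suitability threshold must
  leave eligible planning units for every species, as the study design
  this emulates presumes, including on the smaller desk-scale grids used
  in the test suite. With weaker loading, unit-level occupancy rarely
  exceeds 0.75 on 100-unit landscapes.
* Cell values are statistically calibrated but carry none of the
  parcel/tenure structure, zero-inflation, or model-based smoothness of
  real cadastral and occupancy layers. Passing tests demonstrate the
  algorithmic contracts and the direction of data-value effects under the
  printed summary statistics, not magnitudes that would transfer to any
  particular real landscape.

## Aggregation

Planning units are axis-aligned `factor × factor` blocks anchored at the
grid origin (default factor 10: 1-ha cells → 1-km² units), row-major,
0-based. Cost is summed over the block; occupancy is averaged. Partial
edge blocks are an error rather than smaller units, because mixed unit
areas would distort the unit-count objective. Total cost and
area-weighted mean occupancy are exactly conserved, and two-stage
aggregation composes (`a` then `b` equals `a·b`).

## Relative-CV manipulation

With `CV = SD/μ` (sample SD, `ddof=1`, used consistently package-wide),
the benefit CV is the mean of the per-species occupancy-layer CVs,
computed at planning-unit resolution — the scale the optimizer sees — and
by default over the species subset active in the scenario (one guild).
The cost layer is shifted by the constant

    Δ_cost = CV_relative · SD_cost / CV_benefit − μ_cost

which leaves SD_cost and the cost ordering of units untouched and makes
the achieved ratio CV_benefit/CV_cost equal `CV_relative` exactly (an
algebraic identity the tests assert at 1e−9). Ratios below the raw one
would require a negative shift that can push the cheapest unit below
zero; that case raises an error carrying the offending Δ. The shifted
costs are used both in the objective and in the "fraction of total cost"
reporting, keeping each scenario internally consistent.

## Selection problems

**Eligibility.** A unit counts toward a species only where its mean
occupancy meets the suitability threshold (inclusive ≥, per species);
below-threshold occupancy contributes a zero coefficient rather than
removing the unit, so one unit can serve one species and not another.
The target denominator is the species' occupancy total over *eligible*
units by default (`pre_threshold` is available as an option): with a
pre-threshold denominator, 100% targets are generically unreachable at
high thresholds, whereas the post-threshold reading keeps the full
target ladder meaningful. A species with no eligible units makes the
instance infeasible — there is simply no suitable habitat to protect.

**Minimum-set ILP.** Binary selection variables, minimize `Σ w_i x_i`
(`w` = unit cost, or all ones for the minimum-area variant) subject to
`Σ p_si x_i ≥ target · total_s` per species. Solved with HiGHS
branch-and-bound (via `scipy.optimize.milp`) to a relative optimality
gap, default 1%. Numerical choices:

* the objective is divided by its mean before solving (scale-invariant,
  helps conditioning with costs spanning many orders of magnitude);
* constraint right-hand sides are deflated by a 1e−9 relative slack so a
  100% target, met exactly by the full eligible set, is not lost to
  floating-point summation order; the same slack is used when judging
  feasibility of a returned solution, with a greedy cheapest-unit top-up
  as a guard against looser backend tolerances;
* infeasibility is a first-class solution status, never an exception;
  backend failures raise a distinct solver error;
* an optional per-solve wall-clock cap (`time_limit`) exists because
  cost layers flattened by large relative-CV offsets turn the problem
  into a near-uniform covering problem whose *bound proof* (not whose
  solution) can take minutes; at the cap the incumbent is returned with
  its achieved gap reported, and a status of `time_limit_feasible` when
  that gap exceeds the requested one. Experiment sweeps default to a
  60 s cap.

**C-rank baseline.** Units are added cheapest-first (ties by unit id)
until every target is met; biodiversity data is used only to detect
satisfaction, with the same eligibility accounting as the ILP. The
baseline is deterministic and never beats the exact optimum.

**Brute-force oracle.** Exhaustive subset enumeration (guarded at ≤ 20
units; exact ties broken by lexicographically smallest id tuple) serves
as the independent reference for the solver contract in the tests.

## Efficiency

A cost-benefit curve solves one instance per occupancy target on the
ladder 5–100% in 5% steps (tests use a 10-step ladder where noted) and
records monetary solution cost as a fraction of the total cost of all
units in the scenario's (offset-adjusted) cost layer; minimum-area
solutions are costed monetarily after solving so all methods share a
currency. Efficiency is the trapezoidal area under achieved-target (y)
versus cost-fraction (x), anchored at the origin, with the last feasible
point extended horizontally to x = 1: a curve reaching the full target at
negligible cost has AUC → 1, a diagonal curve has AUC 0.5, and curves
with different feasible support remain comparable (comparisons
additionally restrict to the common feasible target range). The
transposed orientation (area under cost versus target, lower = better) is
exposed as an option. The fractional gain of scenario A over baseline B
is `(AUC_A − AUC_B)/AUC_B`; the two standard comparisons are min-cost vs
minimum-area (value of adding cost data) and min-cost vs C-rank (value of
adding biodiversity data).

## Experiment design and problem sizes

The sweep driver crosses guilds × thresholds {0.25, 0.5, 0.75} ×
relative-CV levels {2, 4, 8, 16} × methods × replicate seeds, generating
one landscape per replicate seed so that all comparisons within a
replicate are paired. Results are tidy CSVs plus a provenance JSON.

Problem sizes are the package's own choices for desk-scale work: the
default landscape is 200×200 fine cells (400 units); the multi-seed
directional suites in the tests run 10 replicates of 80×80-cell
landscapes (64 units) with a 10-step target ladder and a 5 s per-solve
cap, sizes at which all four directional effects are clearly resolved.
The relative-CV comparisons are made at the 75% suitability threshold —
the threshold the CV manipulation is defined to operate at — and the
threshold/target comparisons use the raw (un-rescaled) cost layer. On
small landscapes a guild can lack feasible support at the 75% threshold
for some replicates; those guild/replicate cells are recorded as missing
and directional statistics aggregate over the rest.

## Known limitations

* HiGHS bound-proving on flattened-cost covering instances is slow at
  low thresholds (dense constraint rows); the time-limit mechanism trades
  certified optimality for bounded runtime there and reports the achieved
  gap honestly.
* The generator's cost layer spans ~5 orders of magnitude at the default
  spread, less than extreme real cadastral ranges; the CV — the quantity
  that drives the theory — is matched exactly instead.
* Correlation calibration targets the guild mean only (no across-species
  spread), and occupancy layers are noise-free probabilities with no
  detection/observation error.
* The TIFF writer stores plain single-band rasters (100 m pixel
  resolution tags) without a coordinate reference system; synthetic
  landscapes have no real-world datum.
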