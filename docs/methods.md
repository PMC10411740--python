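# Methods

## System and framing

A cryopeg brine is treated as a closed box of volume-normalised carbon:
particulate organic carbon (POC, P), dissolved organic carbon (DOC, D),
dissolved inorganic carbon (DIC, I) — all in fg C mL⁻¹ — and a bacterial
community of density N cells mL⁻¹. The brine is assumed to have been
enclosed with the carbon pools measured today in its continuously frozen
surroundings, and (for the intra-ice borehole CBIW) to have received one
pulsed addition when it migrated into massive ice. cm³ and mL are treated
as the same unit; days are the internal time unit, with a configurable
`days_per_year = 365.25` (365 reproduces the same three-significant-figure
results).

## Field-measurement conversions

POC: a dry-mass carbon fraction (μg C per μg sediment) becomes an in-situ
concentration via `fraction × (1 − volumetric ice content) × dry sediment
density` (default density 2.625 g mL⁻¹, the kaolinite/sand average). DOC:
a thawed-porewater concentration is mapped back to frozen bulk volume via
`concentration × ice content × (1 − e)`, where e is the freezing
expansion factor (0.0905 for permafrost porewater). The multiplicative
(1 − e) convention is the default because it is the one consistent with
the shipped scenario tables; the alternative 1/(1 + e) convention is
implemented and differs by <1%. Unit scalings (μg→fg = 10⁹, g→fg = 10¹⁵)
live in a single helper module with exact integer factors.

Two candidate values exist for the CB4 surrounding POC: the published
table entry (1.75 × 10¹³ fg C cm⁻³) and the value the conversion chain
yields from the raw CB4 sediment measurement (≈1.69 × 10¹³). The derived
value is the one that reproduces the published CB4 enzyme-rate bounds and
implied timespan; the table value leaves the metabolic-rate bounds ~3%
high. `build_scenario("CB4", p0=...)` exposes both; nothing reconciles
them silently. Similarly, two published CBIW cell densities circulate
(1.39 × 10⁸ and 1.30 × 10⁸ cells mL⁻¹); the preset uses 1.39 × 10⁸, which
matches the published minimum growth rate, while the published doubling
time is the one implied by 1.30 × 10⁸.

## Closed-form bounds

The budget estimator divides consumed carbon by integrated cell-days.
The biomass term α_D(N_f − N₀) is retained even though it is ≤10⁻⁴ of the
numerator for every borehole — exactness costs nothing. The two bounding
trajectories are: no growth (N ≡ N_f, the largest integral a population
ending at N_f can have without exceeding it, hence the lower rate bound)
and the slowest exponential from N₀ = 10⁵ cells mL⁻¹ (upper bound). A
negative numerator (carbon deficit) raises an error rather than clipping:
an infeasible budget is a finding, not a zero.

The implied-timespan inversion solves γ·N₀(e^{μt} − 1)/μ = ΔP for t in
closed form, holding μ at the minimum growth rate computed over the
nominal 40,000-year age even when the solved t exceeds that age. The
procedure is deliberately self-referential — it asks "how long would the
measured enzyme rate need?" as a consistency check on the age — and this
convention is the one that reproduces the published timespans.

Power conversion: fg C cell⁻¹ day⁻¹ × 10⁻¹⁵/12.011 mol C × 30 kJ mol⁻¹ /
86,400 s, the energy yield being a representative heterotrophic catabolic
value (user-settable).

## The carbon-cycle ODE model

State (N, P, D, I); processes: Monod growth μ_max·D/(K_D + D)·N·(1 −
N/N_max); starvation death Δ = max(mN − D, 0)/m, clamped to ≤N (the raw
expression can transiently exceed the population when D ≈ 0; a clamp is
the physically sensible reading and is a documented choice — whether the
original implementation clamped is unknowable from the outputs); EEA flux
min(γ_cell·N, P); respiration m(N − Δ); optional DIC fixation min(I_xr, I)
with hooks α_I, I_xr kept in the equations but zero by default.

Numerics: `scipy.integrate.solve_ivp` with LSODA, rtol 10⁻⁸ for precision
runs, absolute tolerances scaled per state (10⁻³ cells; 1 fg C). Pulsed
additions are discrete state jumps between integration segments, not
derivative spikes, which keeps the solver stable and the mass-balance
audit exact; at each pulse a population below 1 cell mL⁻¹ is rescued to
exactly 1 (a float population never hits exact zero). Inside the
right-hand side, transiently negative states are floored at zero for rate
evaluation only; because all four equations use the same floored values,
the conservation identity d(P + D + I + α_D N)/dt = inputs cancels
algebraically regardless. Reported states are clipped at zero. The audit
(`mass_balance_audit`) checks total carbon against cumulative additions
(including the α_D·rescue biomass) and sits at ~10⁻¹⁴ relative in
practice, against a 10⁻⁶ test budget.

Accuracy tiers: precision runs (oracle comparisons, conservation checks)
use rtol 10⁻⁸–10⁻¹¹; the 24-run bound grid uses 10⁻⁶ and the sensitivity
draws 10⁻⁵, which changes no classification and keeps both stages at
desk scale (the grid completes in under a second; a converged Sobol run
in minutes).

Initial conditions: N = N₀, P and D equal to the surrounding-sediment
pools, I = 0 (no brine DIC initial value is published; configurable).

## Simulation grid and outcome classification

The 2×2×2 grid crosses growth rate (μ_min vs lab μ_max), metabolic rate
(budget lower vs upper bound) and EEA rate (calculated vs measured
1.22 × 10⁻² fg C cell⁻¹ day⁻¹). The "calculated" EEA rate is the budget
upper bound — the rate required to feed a growing population — because
that is the choice under which the slow-growth/low-maintenance corner
reaches the observed densities for all three boreholes; the no-growth
value is selectable. Outcomes: `reaches_observed` within a factor of 2 of
N_f (an order-of-magnitude study; factor 2 is deliberately generous),
`collapse` below 1 cell mL⁻¹, `partial_recovery` when a post-pulse rise
still falls short, `plateau_decline` otherwise. The grid has no
stochastic elements and re-runs bit-identically.

## Sobol sensitivity analysis

Implemented from first principles on `scipy.stats.qmc.Sobol` (scrambled)
with Saltelli paired matrices A, B, AB_i and Jansen estimators;
percentile bootstrap CIs (default 1,000 resamples, 95% confidence); the
base sample doubles until every CI half-width meets a target or a cap is
reached, in which case the result is returned flagged `converged=False`.
The estimator is validated against closed forms (additive function,
Ishigami) in the test suite.

Seven microbial parameters of the CB1 scenario are varied; environmental
pools stay fixed. The published bounds are used verbatim even where they
sit oddly against the scenario tables (cell carbon content 10²–5 × 10²
fg C vs the 15.7–54 actually used; metabolic rate up to 5 × 10² vs bounds
≤0.743). Growth rate (10⁻⁶–10²) and metabolic rate (10⁻⁵–5 × 10²) are
sampled log-uniformly: uniform sampling of a 7–8-decade rate range puts
essentially all mass in the top decade, and empirically every such draw
collapses (output variance exactly zero, indices undefined). The
remaining parameters are uniform. Draws whose integration fails, or whose
endpoint exceeds its physical cap (carrying capacity for N; initial POC
for P — a numerical blow-up signature), are assigned the collapse outcome
(0) so the paired matrices stay aligned.

Observed pattern (seeded runs in the test suite): the maintenance demand
m dominates the first-order variance of final cell density; cell carbon
content, starting density and the EEA rate have no notable direct effect;
the EEA rate's first-order index is distinctly larger for the final POC
pool, which it alone drains. Growth rate and half-velocity constant
register only in total-effect terms under this design. A stronger
three-way prominence of growth rate, maintenance rate and half-velocity
constant has been reported for this model family; under the sampling
designs testable here (uniform being degenerate, log-uniform otherwise)
that full pattern does not emerge, and the tests assert only the pattern
this analysis actually produces.

The output metric defaults to final cell density N(t_f), with final POC
P(t_f) as the alternative.

## Synthetic data

`generate_scenario` forward-simulates the model under known parameters
and emits exactly what a field campaign observes: surrounding pools (=
initial pools), brine pools and cell density at the endpoint, each
optionally perturbed by multiplicative lognormal noise (concentrations
are positive and errors scale-proportional). Ground truth is serialized
alongside so tests never re-derive it. A spec whose population collapses
below 1 cell mL⁻¹ is rejected as infeasible. `perturb_tables` resamples
scenario-table entries at a given relative sd to propagate
rounding-scale input uncertainty; at 3% it spans both candidate CB4
lower bounds, reproducing that discrepancy as rounding-scale.

What the generator does not emulate: real measurement processes (CHN
analysis, DIC mass spectrometry), spatial heterogeneity, community
composition, or time-varying enzyme kinetics. Passing recovery tests
therefore show the estimators are self-consistent under the model's own
assumptions — not that those assumptions hold in a real brine.

## Known limitations

- No diffusion or spatial niches; uniform cells (same growth rate, same
  carbon content); death only by starvation beyond what the net growth
  rate absorbs; EEA rate constant in time.
- DIC is a pure respiration accumulator: the model overpredicts the
  measured CBIW DIC by ~10^2.4 (the full-budget run), pointing at
  unmodelled inorganic-carbon sinks rather than at the organic budget.
- The energetics bounds inherit the assumed starting density
  N₀ = 10⁵ cells mL⁻¹ and the equal-carbon enclosure assumption; the
  sensitivity analysis shows N₀ itself is not a driver of model output.
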