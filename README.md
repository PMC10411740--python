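# cryocarbon

Energetics of bacterial communities in ancient subzero brines.

Cryopeg brines are pockets of hypersaline liquid water that persist below
0 °C inside Arctic permafrost. The system modelled here (Utqiaġvik,
Alaska) has been hydrologically isolated for roughly 40,000 years, yet its
brines hold 10⁵–10⁸ bacterial cells per mL. `cryocarbon` asks how a closed
pool of organic carbon can have paid that community's energy bill, and
answers with three connected analyses:

1. **Closed-form energetics bounds.** Treating the brine as a closed
   carbon budget, the cell-specific metabolic rate *m* (all per-cell
   carbon use except biomass) is

   *m* = [(S₀ + Sᵢ) − S_f − α_D(N_f − N₀)] / ∫₀^{t_f} N(t) dt

   where S = POC + DOC, α_D is carbon per cell, and N(t) is the unknown
   cell-density trajectory. Two bounding trajectories bracket the
   integral: no growth (constant at the observed density N_f) and the
   slowest exponential from an assumed N₀ = 10⁵ cells mL⁻¹ to N_f. The
   same construction on the POC pool alone bounds the cell-specific
   extracellular enzyme activity (EEA) rate γ_cell, and inverting it at
   the measured EEA rate predicts the system's age.

2. **An ODE model of the brine carbon cycle.** Monod growth with a
   logistic cap, starvation death, constant per-cell EEA hydrolysing POC
   to DOC, respiration of DOC to DIC, and pulsed carbon additions (the
   intra-ice brine CBIW received one when it migrated into massive ice
   ~11,000 years BP). A 2×2×2 grid over growth-rate, metabolic-rate and
   EEA bounds tests which energetic histories reach the observed
   densities.

3. **Sobol global sensitivity analysis** of the model over broad
   microbial-parameter bounds, with a paired-matrix (Saltelli) design,
   Jansen estimators and bootstrap confidence intervals.

A synthetic-data module generates fake boreholes with known ground truth
so every estimator is testable end to end, including noise-propagation
and coverage experiments.

## Worked example

```python
from cryocarbon import build_scenario, compute_bounds, watts_per_cell

scenario, constants = build_scenario("CB1")
b = compute_bounds(scenario, constants)
print(f"minimum growth rate  {b.mu_min:.3g} /day")
print(f"doubling time        {b.doubling_time:,.0f} years")
print(f"metabolic rate       {b.m_lower:.3g} - {b.m_upper:.3g} fg C/cell/day")
print(f"EEA rate             {b.gamma_lower:.3g} - {b.gamma_upper:.3g} fg C/cell/day")
print(f"implied timespan     {b.implied_timespan:,.0f} years")
print(f"power per cell       {watts_per_cell(b.m_upper):.2g} W")
```

prints

```
minimum growth rate  2.77e-07 /day
doubling time        6,858 years
metabolic rate       0.181 - 0.744 fg C/cell/day
EEA rate             0.195 - 0.803 fg C/cell/day
implied timespan     81,252 years
power per cell       2.2e-17 W
```

Reading: connecting 10⁵ to the observed 5.7 × 10⁶ cells mL⁻¹ over 40,000
years needs a growth rate of only 2.77 × 10⁻⁷ day⁻¹ (a doubling every
~6,900 years); the carbon budget then allows each cell 0.18–0.74 fg C per
day, of order 10⁻¹⁷ W — high for an energy-limited subsurface habitat,
consistent with the cost of making extracellular enzymes and
cryoprotective polysaccharides. At the EEA rate actually measured in
brine, hydrolysing the missing POC would take ~81,000 years, twice the
radiocarbon age: the historical enzyme activity must have been higher
than measured today.

The same numbers come from the command line:

```sh
cryocarbon bounds --scenario CB1
cryocarbon grid --scenario CBIW --out results/grid
cryocarbon sensitivity --scenario CB1 --output final_N --seed 1
```

## Analysis scripts

The full study is laid out as numbered drivers over the library, each
writing tidy CSV tables under `results/`:

| script | what it does |
| --- | --- |
| `analysis/01_field_measurements.py` | raw sediment measurements → in-situ carbon concentrations |
| `analysis/02_energetics_bounds.py` | the headline energetics table for all boreholes |
| `analysis/03_simulation_grid.py` | 24 carbon-cycle runs, outcome classification, DIC comparison |
| `analysis/04_sensitivity.py` | Sobol indices for final cell density and final POC |
| `analysis/05_synthetic_recovery.py` | bound coverage under noise; table-rounding propagation |

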