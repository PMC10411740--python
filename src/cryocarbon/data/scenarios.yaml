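# Borehole scenario presets for the Utqiagvik cryopeg system, plus the
# shared model constants and the raw frozen-sediment measurements they
# derive from.  Units follow the field convention: carbon pools in
# fg C mL^-1 (brine) or fg C cm^-3 (frozen surroundings; cm^3 == mL),
# densities in cells mL^-1, rates in day^-1 or fg C cell^-1 day^-1.
# Users can add boreholes by appending entries of the same shape.

constants:
  N_max: 1.0e+9          # carrying capacity, cells mL^-1
  K_D: 8.82e+5           # Monod half-velocity constant, fg C mL^-1
  N_0: 1.0e+5            # assumed starting cell density, cells mL^-1
  gamma_measured: 1.22e-2  # measured cell-specific EEA rate, fg C cell^-1 day^-1
  t_f: 40000.0           # system age / simulation timespan, years
  alpha_I: 0.0           # DIC per cell (autotrophy hook, off)
  I_xr: 0.0              # DIC fixation rate (autotrophy hook, off)
  days_per_year: 365.25

# CHN-analyzer / DOC-analyzer outputs on archived frozen material.
# poc_mass_fraction: ug C per ug dry sediment; porewater_doc: ug C per mL
# thawed porewater; dry_sediment_density: g mL^-1; expansion_factor is the
# ice->water volume change applied to thaw-based concentrations.
raw_measurements:
  BEO:
    poc_mass_fraction: 0.0232
    porewater_doc: 51.2
    volumetric_ice_content: 0.731
    dry_sediment_density: 2.625
    expansion_factor: 0.0905
  CB4:
    poc_mass_fraction: 0.0136
    porewater_doc: 1286.0
    volumetric_ice_content: 0.527
    dry_sediment_density: 2.625
    expansion_factor: 0.0905

scenarios:
  CB1:
    N_f: 5.70e+6
    P_0: 1.64e+13        # regional (BEO) frozen sediment POC
    D_0: 3.41e+10
    P_f: 1.49e+11
    D_f: 1.23e+12
    D_in: 0.0
    P_in: 0.0
    addition_time: null
    alpha_D: 15.7
    mu_max: 0.06
  CB4:
    N_f: 1.14e+7
    P_0: 1.75e+13        # published value; see build_scenario(p0="derived")
    D_0: 6.17e+11
    P_f: 4.97e+10
    D_f: 1.02e+12
    D_in: 0.0
    P_in: 0.0
    addition_time: null
    alpha_D: 54.04
    mu_max: 0.016
  CBIW:
    N_f: 1.39e+8
    P_0: 1.64e+13        # intra-ice brine assumed to start in BEO-like sediment
    D_0: 3.41e+10
    P_f: 2.38e+10
    D_f: 3.60e+11
    D_in: 3.88e+10       # pulsed addition when brine migrated into massive ice
    P_in: 1.86e+10
    addition_time: 29000.0   # years since enclosure (40,000 - 11,000 BP)
    alpha_D: 15.7
    mu_max: 0.06
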