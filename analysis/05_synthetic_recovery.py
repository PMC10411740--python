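#!/usr/bin/env python
"""Validate the estimators on synthetic brines with known ground truth.

Two experiments: (1) generate 200 noisy synthetic field campaigns from a
plateau-growth brine and check how often the closed-form metabolic-rate
bounds bracket the true rate; (2) propagate 1% and 3% table-rounding
uncertainty through the estimators for the real boreholes.

Found: with 5% lognormal observation noise the bounds cover the true
maintenance rate in ~99% of campaigns.  A 1% input uncertainty moves the
CB1 lower bound by ~1% (the budget is linear in its dominant POC entry),
and 3% uncertainty on the CB4 table spans both published candidate lower
bounds (0.099 and 0.102), reproducing that discrepancy as rounding-scale.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cryocarbon.bounds import GrowthTrajectory, compute_bounds, metabolic_rate
from cryocarbon.field_data import build_scenario
from cryocarbon.synthetic import SyntheticSpec, generate_scenario, perturb_tables

RESULTS = Path(__file__).resolve().parents[1] / "results"

PLATEAU = dict(
    mu=4.5e-7, m=0.2, gamma_cell=0.35, alpha_D=15.7,
    N_0=1e5, P_0=1.64e13, D_0=3.41e10, N_max=5e6, t_f=40_000.0,
)


def coverage_experiment(n_draws: int, seed0: int) -> dict:
    t_days = PLATEAU["t_f"] * 365.25
    covered = infeasible = 0
    for k in range(n_draws):
        spec = SyntheticSpec(**PLATEAU, pool_noise_sd=0.05,
                             density_noise_sd=0.05, seed=seed0 + k)
        observed, truth, _ = generate_scenario(spec)
        flat = GrowthTrajectory.no_growth(observed.N_f, t_days)
        expo = GrowthTrajectory.slowest_exponential(truth.N_0, observed.N_f,
                                                    t_days)
        try:
            lo, hi = metabolic_rate(observed, flat), metabolic_rate(observed, expo)
        except ValueError:
            infeasible += 1
            continue
        covered += lo <= truth.m <= hi
    return {"draws": n_draws, "covered": covered, "infeasible": infeasible,
            "coverage": covered / n_draws}


def perturbation_experiment(seed0: int) -> pd.DataFrame:
    rows = []
    for name, rel_sd in (("CB1", 0.01), ("CB4", 0.03)):
        scenario, constants = build_scenario(name)
        lowers = []
        for k in range(100):
            perturbed = perturb_tables(scenario, rel_sd, seed=seed0 + k)
            try:
                lowers.append(compute_bounds(perturbed, constants).m_lower)
            except ValueError:
                continue
        lowers = np.array(lowers)
        rows.append(
            {"scenario": name, "rel_sd": rel_sd,
             "m_lower_mean": lowers.mean(), "m_lower_sd": lowers.std(),
             "m_lower_min": lowers.min(), "m_lower_max": lowers.max()}
        )
    return pd.DataFrame(rows)


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--draws", type=int, default=200)
    args = parser.parse_args()

    RESULTS.mkdir(exist_ok=True)
    cov = coverage_experiment(args.draws, args.seed)
    print(f"bound coverage of true m under 5% noise: "
          f"{cov['coverage']:.1%} of {cov['draws']} campaigns "
          f"({cov['infeasible']} infeasible)")
    pd.DataFrame([cov]).to_csv(RESULTS / "synthetic_coverage.csv", index=False)

    table = perturbation_experiment(args.seed)
    table.to_csv(RESULTS / "table_perturbation.csv", index=False)
    with pd.option_context("display.float_format", "{:.4g}".format):
        print(table.to_string(index=False))
    print("wrote synthetic_coverage.csv and table_perturbation.csv")


if __name__ == "__main__":
    main()
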