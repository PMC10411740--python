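"""Bound-combination simulation grid and trajectory-outcome classification.

For each borehole scenario the carbon-cycle model is run under all 8
combinations of lower/upper bounds of three rates: growth rate (the
minimum exponential rate vs the lab-measured maximum), cell-specific
metabolic rate (its budget lower vs upper bound), and cell-specific EEA
rate (the budget-calculated value vs the rate measured in brine,
1.22e-2 fg C cell^-1 day^-1).  Each run is classified against the observed
present-day cell density, reproducing the qualitative outcome narrative:
only the slow-growth / low-maintenance corner of the grid can reach the
observed densities, and only when enzyme activity supplies DOC at least as
fast as cells consume it.

The "calculated" EEA rate in a grid cell is the budget upper bound (the
rate required to feed a growing population, e.g. 0.802 fg C cell^-1 day^-1
for CB1); the no-growth value can be selected via ``calculated_eea``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

from .bounds import BoundsResult, compute_bounds
from .carbon_model import Trajectory, params_from_scenario, simulate_scenario
from .field_data import ModelConstants, ScenarioDefinition

__all__ = [
    "GridCombination",
    "OutcomeReport",
    "grid_combinations",
    "run_combination",
    "run_grid",
    "classify_outcome",
    "dic_comparison",
]

#: reaches_observed means final density within this factor of the observed
#: one (order-of-magnitude study; a factor of two is deliberately generous).
REACH_FACTOR = 2.0

#: collapse means fewer than one cell per mL at the end of the run.
COLLAPSE_DENSITY = 1.0


@dataclass(frozen=True)
class GridCombination:
    """One corner of the 2x2x2 bound grid."""

    growth_case: str      # "minimum" | "maximum"
    metabolic_case: str   # "lower" | "upper"
    eea_case: str         # "calculated" | "measured"

    def __post_init__(self) -> None:
        if self.growth_case not in ("minimum", "maximum"):
            raise ValueError(f"bad growth_case {self.growth_case!r}")
        if self.metabolic_case not in ("lower", "upper"):
            raise ValueError(f"bad metabolic_case {self.metabolic_case!r}")
        if self.eea_case not in ("calculated", "measured"):
            raise ValueError(f"bad eea_case {self.eea_case!r}")

    @property
    def label(self) -> str:
        return f"{self.growth_case}-{self.metabolic_case}-{self.eea_case}"


@dataclass(frozen=True)
class OutcomeReport:
    """Classified endpoint of one grid run."""

    scenario: str
    combination: GridCombination
    final_N: float
    final_P: float
    final_D: float
    final_I: float
    classification: str
    reached_fraction: float

    def as_dict(self) -> dict:
        d = {
            "scenario": self.scenario,
            "combination": self.combination.label,
            "growth_case": self.combination.growth_case,
            "metabolic_case": self.combination.metabolic_case,
            "eea_case": self.combination.eea_case,
            "final_N": self.final_N,
            "final_P": self.final_P,
            "final_D": self.final_D,
            "final_I": self.final_I,
            "classification": self.classification,
            "reached_fraction": self.reached_fraction,
        }
        return d


def grid_combinations() -> list[GridCombination]:
    """The 8 distinct bound combinations, in a fixed deterministic order."""
    return [
        GridCombination(g, m, e)
        for g, m, e in itertools.product(
            ("minimum", "maximum"), ("lower", "upper"), ("calculated", "measured")
        )
    ]


def _select_rates(
    comb: GridCombination,
    scenario: ScenarioDefinition,
    constants: ModelConstants,
    bounds: BoundsResult,
    calculated_eea: str,
) -> tuple[float, float, float]:
    mu = bounds.mu_min if comb.growth_case == "minimum" else scenario.mu_max
    m = bounds.m_lower if comb.metabolic_case == "lower" else bounds.m_upper
    if comb.eea_case == "measured":
        gamma = constants.gamma_measured
    else:
        gamma = (
            bounds.gamma_upper if calculated_eea == "exponential"
            else bounds.gamma_lower
        )
    return mu, m, gamma


def run_combination(
    scenario: ScenarioDefinition,
    constants: ModelConstants,
    comb: GridCombination,
    bounds: Optional[BoundsResult] = None,
    calculated_eea: str = "exponential",
    rtol: float = 1e-6,
    **solver_kwargs,
) -> tuple[Trajectory, "OutcomeReport"]:
    """Simulate one grid combination and classify its outcome."""
    if bounds is None:
        bounds = compute_bounds(scenario, constants)
    mu, m, gamma = _select_rates(comb, scenario, constants, bounds, calculated_eea)
    params = params_from_scenario(scenario, constants, mu_max=mu, m=m,
                                  gamma_cell=gamma)
    traj = simulate_scenario(scenario, constants, params, rtol=rtol,
                             **solver_kwargs)
    report = OutcomeReport(
        scenario=scenario.name,
        combination=comb,
        final_N=traj.N[-1],
        final_P=traj.P[-1],
        final_D=traj.D[-1],
        final_I=traj.I[-1],
        classification=classify_outcome(traj, scenario.N_f),
        reached_fraction=traj.N[-1] / scenario.N_f,
    )
    return traj, report


def run_grid(
    scenario: ScenarioDefinition,
    constants: ModelConstants,
    calculated_eea: str = "exponential",
    rtol: float = 1e-6,
    **solver_kwargs,
) -> list[OutcomeReport]:
    """Run all 8 bound combinations for one scenario (deterministic)."""
    bounds = compute_bounds(scenario, constants)
    reports = []
    for comb in grid_combinations():
        _, report = run_combination(
            scenario, constants, comb, bounds=bounds,
            calculated_eea=calculated_eea, rtol=rtol, **solver_kwargs,
        )
        reports.append(report)
    return reports


def classify_outcome(traj: Trajectory, N_f_observed: float) -> str:
    """Classify a trajectory endpoint against the observed cell density.

    ``reaches_observed``
        final density within a factor of REACH_FACTOR of the observation;
    ``collapse``
        fewer than one cell per mL remains;
    ``partial_recovery``
        the population rose after a pulsed addition but still fell short;
    ``plateau_decline``
        everything else (grows weakly or plateaus, then declines).
    """
    final = traj.N[-1]
    ratio = final / N_f_observed
    if 1.0 / REACH_FACTOR <= ratio <= REACH_FACTOR:
        return "reaches_observed"
    if final < COLLAPSE_DENSITY:
        return "collapse"
    for t_event, _, _ in traj.events:
        post = traj.N[traj.times >= t_event]
        if len(post) > 1 and post.max() > post[0] * 1.5:
            return "partial_recovery"
    return "plateau_decline"


def dic_comparison(traj: Trajectory, measured_dic: float) -> dict:
    """Compare modeled end-of-run DIC against a measured brine value.

    Returns the modeled final DIC, the measurement, and their log10 ratio
    (NaN-flagged when either is nonpositive).  Used to gauge how strongly
    the closed-system respiration budget overpredicts standing DIC.
    """
    modeled = float(traj.I[-1])
    if modeled <= 0 or measured_dic <= 0:
        return {"modeled_dic": modeled, "measured_dic": measured_dic,
                "log10_ratio": math.nan, "defined": False}
    return {
        "modeled_dic": modeled,
        "measured_dic": measured_dic,
        "log10_ratio": math.log10(modeled / measured_dic),
        "defined": True,
    }
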