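"""Synthetic borehole scenarios with known ground truth.

A field campaign observes a cryopeg brine only at its endpoints: the
carbon pools of the frozen surroundings (taken as the starting inventory),
the present-day brine pools, and the present-day cell density.  This
module forward-simulates the carbon-cycle model under known ("true")
parameters and emits exactly that observation set — optionally perturbed
by multiplicative lognormal measurement noise — so the closed-form
estimators and the ODE model can be tested end-to-end without any field
data, including parameter-recovery and noise-propagation experiments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from ._units import DAYS_PER_YEAR
from .carbon_model import (
    Addition,
    ModelParameters,
    ModelState,
    Trajectory,
    simulate,
)
from .field_data import ModelConstants, ScenarioDefinition

__all__ = ["SyntheticSpec", "GroundTruth", "generate_scenario", "perturb_tables"]


@dataclass(frozen=True)
class SyntheticSpec:
    """True parameters and observation-noise levels for one synthetic brine.

    Noise standard deviations are relative (lognormal sigma of the
    multiplicative error) and apply to the observed pools and the final
    cell density; zero noise reproduces the model output exactly.
    """

    mu: float                  # day^-1, realised net growth rate
    m: float                   # fg C cell^-1 day^-1
    gamma_cell: float          # fg C cell^-1 day^-1
    alpha_D: float = 15.7
    N_0: float = 1.0e5
    P_0: float = 1.64e13
    D_0: float = 3.41e10
    t_f: float = 40_000.0      # years
    K_D: float = 8.82e5
    N_max: float = 1.0e9
    D_in: float = 0.0
    P_in: float = 0.0
    addition_time: Optional[float] = None  # years
    pool_noise_sd: float = 0.0
    density_noise_sd: float = 0.0
    days_per_year: float = DAYS_PER_YEAR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_noise_sd < 0 or self.density_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.t_f <= 0:
            raise ValueError("t_f must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """True parameters and noiseless endpoints behind a synthetic scenario."""

    mu: float
    m: float
    gamma_cell: float
    alpha_D: float
    N_0: float
    t_f: float
    true_N_f: float
    true_P_f: float
    true_D_f: float
    true_I_f: float

    def to_json(self, path: Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _lognormal_factor(rng: np.random.Generator, sd: float) -> float:
    if sd == 0:
        return 1.0
    return float(rng.lognormal(mean=0.0, sigma=sd))


def generate_scenario(
    spec: SyntheticSpec, rtol: float = 1e-8
) -> tuple[ScenarioDefinition, GroundTruth, Trajectory]:
    """Forward-simulate a synthetic brine and observe it like a campaign.

    Returns the observed :class:`ScenarioDefinition` (surrounding pools =
    initial pools, brine pools and N_f = noise-perturbed final state), the
    noiseless :class:`GroundTruth`, and the full model trajectory.

    Raises ``ValueError`` if the synthetic population collapses before
    ``t_f`` (fewer than one cell per mL), since the observation model then
    has no community left to measure.
    """
    additions: tuple[Addition, ...] = ()
    if spec.addition_time is not None:
        additions = (
            Addition(
                time=spec.addition_time * spec.days_per_year,
                D_in=spec.D_in, P_in=spec.P_in,
            ),
        )
    params = ModelParameters(
        mu_max=spec.mu, m=spec.m, gamma_cell=spec.gamma_cell,
        alpha_D=spec.alpha_D, K_D=spec.K_D, N_max=spec.N_max,
        additions=additions,
    )
    initial = ModelState(N=spec.N_0, P=spec.P_0, D=spec.D_0, I=0.0)
    traj = simulate(params, initial, spec.t_f * spec.days_per_year, rtol=rtol)
    final = traj.final_state
    if final.N < 1.0:
        raise ValueError(
            f"infeasible synthetic spec: population collapsed "
            f"(final N = {final.N:.3g} cells/mL)"
        )

    rng = np.random.default_rng(spec.seed)
    observed = ScenarioDefinition(
        name=f"synthetic-{spec.seed}",
        N_f=final.N * _lognormal_factor(rng, spec.density_noise_sd),
        P_0=spec.P_0 * _lognormal_factor(rng, spec.pool_noise_sd),
        D_0=spec.D_0 * _lognormal_factor(rng, spec.pool_noise_sd),
        P_f=final.P * _lognormal_factor(rng, spec.pool_noise_sd),
        D_f=final.D * _lognormal_factor(rng, spec.pool_noise_sd),
        D_in=spec.D_in,
        P_in=spec.P_in,
        addition_time=spec.addition_time,
        alpha_D=spec.alpha_D,
        mu_max=spec.mu,
        notes="synthetic scenario with serialized ground truth",
    )
    truth = GroundTruth(
        mu=spec.mu, m=spec.m, gamma_cell=spec.gamma_cell,
        alpha_D=spec.alpha_D, N_0=spec.N_0, t_f=spec.t_f,
        true_N_f=final.N, true_P_f=final.P, true_D_f=final.D,
        true_I_f=final.I,
    )
    return observed, truth, traj


def perturb_tables(
    scenario: ScenarioDefinition, rel_sd: float, seed: int
) -> ScenarioDefinition:
    """Resample a scenario's carbon pools within a relative uncertainty.

    Published scenario tables round to three significant figures; this
    draws one lognormal perturbation per pool entry (P_0, D_0, P_f, D_f,
    pulses) to propagate that rounding-scale uncertainty through the
    closed-form estimators.  ``rel_sd = 0`` returns the scenario unchanged.
    """
    if rel_sd < 0:
        raise ValueError("rel_sd must be >= 0")
    if rel_sd == 0:
        return scenario
    rng = np.random.default_rng(seed)

    def jitter(x: float) -> float:
        return x * _lognormal_factor(rng, rel_sd) if x > 0 else x

    return replace(
        scenario,
        P_0=jitter(scenario.P_0),
        D_0=jitter(scenario.D_0),
        P_f=jitter(scenario.P_f),
        D_f=jitter(scenario.D_f),
        D_in=jitter(scenario.D_in),
        P_in=jitter(scenario.P_in),
    )
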