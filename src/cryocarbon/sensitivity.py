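"""Sobol variance-based global sensitivity analysis of the carbon model.

First-order indices S_i measure the fraction of output variance
attributable to parameter i alone; total-effect indices ST_i include its
interactions.  The estimator follows the paired-matrix (Saltelli) design:
two quasi-random sample matrices A and B of size N x d are drawn from a
scrambled Sobol sequence, plus the d radial matrices AB_i (A with column i
taken from B); with f evaluated on all of them, the Jansen estimators are

    S_i  = ( V - mean[(f(B) - f(AB_i))^2] / 2 ) / V
    ST_i =       mean[(f(A) - f(AB_i))^2] / 2   / V

with V the variance of f over A u B.  Confidence intervals come from a
seeded bootstrap over sample rows; the analysis doubles the base sample
until every CI half-width meets a target at >= 95% confidence, or a cap
is hit (then ``converged=False`` is returned rather than an error).

The default analysis varies the seven microbial parameters of the CB1
scenario over broad plausibility bounds (environmental pools held fixed)
and reads out the final cell density N(t_f); the final POC pool P(t_f) is
the alternative output.  Model draws whose integration fails are assigned
the collapse outcome (output 0) so the paired matrices stay aligned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

from .carbon_model import ModelParameters, ModelState, simulate
from .field_data import ModelConstants, ScenarioDefinition

__all__ = [
    "ParameterRange",
    "SensitivitySpec",
    "SobolResult",
    "default_parameter_ranges",
    "sobol_indices",
    "sobol_analysis",
    "make_scenario_output",
]


@dataclass(frozen=True)
class ParameterRange:
    """One analysed parameter with its plausibility bounds.

    ``scale="log"`` samples log-uniformly; used for rates whose bounds span
    four or more decades, where uniform sampling would collapse onto the
    top decade.
    """

    name: str
    lower: float
    upper: float
    scale: str = "uniform"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper")
        if self.scale not in ("uniform", "log"):
            raise ValueError(f"{self.name}: scale must be 'uniform' or 'log'")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log scale needs positive bounds")

    def transform(self, u: np.ndarray) -> np.ndarray:
        """Map unit-interval samples onto the bounded range."""
        if self.scale == "log":
            return self.lower * (self.upper / self.lower) ** u
        return self.lower + (self.upper - self.lower) * u


def default_parameter_ranges() -> list[ParameterRange]:
    """Microbial-parameter bounds of the default analysis.

    Growth rate and metabolic rate span >= 7 decades and are sampled
    log-uniformly; the remaining parameters uniformly.
    """
    return [
        ParameterRange("mu_max", 1e-6, 1e2, scale="log"),
        ParameterRange("m", 1e-5, 5e2, scale="log"),
        ParameterRange("alpha_D", 1e2, 5e2),
        ParameterRange("gamma_cell", 0.0, 1e2),
        ParameterRange("K_D", 1e3, 1e8),
        ParameterRange("N_max", 1e8, 1e9),
        ParameterRange("N_0", 1.0, 1e8),
    ]


@dataclass(frozen=True)
class SensitivitySpec:
    """Configuration of one Sobol analysis run."""

    parameters: tuple[ParameterRange, ...]
    output_metric: str = "final_N"
    base_samples: int = 64
    max_samples: int = 1024
    confidence_level: float = 0.95
    ci_halfwidth_target: float = 0.1
    bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.confidence_level < 0.95:
            raise ValueError("confidence_level must be at least 0.95")
        if self.output_metric not in ("final_N", "final_P"):
            raise ValueError("output_metric must be 'final_N' or 'final_P'")
        if self.base_samples < 4 or self.max_samples < self.base_samples:
            raise ValueError("need 4 <= base_samples <= max_samples")
        object.__setattr__(self, "parameters", tuple(self.parameters))


@dataclass(frozen=True)
class SobolResult:
    """First-order and total-effect indices with bootstrap CIs."""

    names: tuple[str, ...]
    first_order: np.ndarray
    total_effect: np.ndarray
    first_ci: np.ndarray    # (d, 2) lower/upper
    total_ci: np.ndarray
    samples_used: int
    converged: bool
    output_metric: str = "final_N"

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "parameter": self.names,
                "first_order": self.first_order,
                "first_lo": self.first_ci[:, 0],
                "first_hi": self.first_ci[:, 1],
                "total_effect": self.total_effect,
                "total_lo": self.total_ci[:, 0],
                "total_hi": self.total_ci[:, 1],
            }
        )

    def index_of(self, name: str) -> int:
        return self.names.index(name)


def _jansen(f_a: np.ndarray, f_b: np.ndarray, f_ab: np.ndarray):
    """Jansen estimators given f(A) (n,), f(B) (n,), f(AB_i) (d, n)."""
    allf = np.concatenate([f_a, f_b])
    variance = allf.var()
    if variance == 0:
        d = f_ab.shape[0]
        return np.zeros(d), np.zeros(d)
    first = (variance - 0.5 * np.mean((f_b[None, :] - f_ab) ** 2, axis=1)) / variance
    total = 0.5 * np.mean((f_a[None, :] - f_ab) ** 2, axis=1) / variance
    return first, total


def _bootstrap_ci(
    f_a: np.ndarray,
    f_b: np.ndarray,
    f_ab: np.ndarray,
    n_boot: int,
    confidence: float,
    rng: np.random.Generator,
):
    n = len(f_a)
    d = f_ab.shape[0]
    firsts = np.empty((n_boot, d))
    totals = np.empty((n_boot, d))
    for k in range(n_boot):
        idx = rng.integers(0, n, size=n)
        firsts[k], totals[k] = _jansen(f_a[idx], f_b[idx], f_ab[:, idx])
    alpha = (1.0 - confidence) / 2.0
    q = [100 * alpha, 100 * (1 - alpha)]
    first_ci = np.percentile(firsts, q, axis=0).T
    total_ci = np.percentile(totals, q, axis=0).T
    return first_ci, total_ci


def _saltelli_points(
    ranges: Sequence[ParameterRange], n: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scrambled-Sobol A, B and radial AB_i matrices in parameter space."""
    d = len(ranges)
    sampler = qmc.Sobol(d=2 * d, scramble=True, rng=np.random.default_rng(seed))
    unit = sampler.random(n)
    a_unit, b_unit = unit[:, :d], unit[:, d:]
    cols = [r.transform(a_unit[:, j]) for j, r in enumerate(ranges)]
    a = np.column_stack(cols)
    b = np.column_stack([r.transform(b_unit[:, j]) for j, r in enumerate(ranges)])
    ab = np.empty((d, n, d))
    for i in range(d):
        ab[i] = a
        ab[i][:, i] = b[:, i]
    return a, b, ab


def sobol_indices(
    func: Callable[[np.ndarray], float],
    ranges: Sequence[ParameterRange],
    n: int,
    seed: int = 0,
    bootstrap: int = 1000,
    confidence: float = 0.95,
) -> SobolResult:
    """Single-pass Sobol index estimation at base sample size ``n``."""
    a, b, ab = _saltelli_points(ranges, n, seed)
    f_a = np.array([func(row) for row in a], dtype=float)
    f_b = np.array([func(row) for row in b], dtype=float)
    f_ab = np.array(
        [[func(row) for row in ab[i]] for i in range(len(ranges))], dtype=float
    )
    first, total = _jansen(f_a, f_b, f_ab)
    rng = np.random.default_rng(seed + 1)
    first_ci, total_ci = _bootstrap_ci(f_a, f_b, f_ab, bootstrap, confidence, rng)
    return SobolResult(
        names=tuple(r.name for r in ranges),
        first_order=first,
        total_effect=total,
        first_ci=first_ci,
        total_ci=total_ci,
        samples_used=n,
        converged=True,
    )


def sobol_analysis(
    spec: SensitivitySpec,
    func: Callable[[np.ndarray], float],
) -> SobolResult:
    """Sobol analysis with sample-doubling until CIs meet the target.

    ``func`` maps one parameter vector (ordered as ``spec.parameters``) to
    a scalar output.  Convergence means every bootstrap CI half-width, for
    both index families, is at most ``spec.ci_halfwidth_target``.
    """
    n = spec.base_samples
    result = None
    while True:
        result = sobol_indices(
            func, spec.parameters, n, seed=spec.seed,
            bootstrap=spec.bootstrap, confidence=spec.confidence_level,
        )
        halfwidths = np.concatenate(
            [
                (result.first_ci[:, 1] - result.first_ci[:, 0]) / 2,
                (result.total_ci[:, 1] - result.total_ci[:, 0]) / 2,
            ]
        )
        converged = bool(np.all(halfwidths <= spec.ci_halfwidth_target))
        if converged or n >= spec.max_samples:
            return replace(
                result, converged=converged, output_metric=spec.output_metric
            )
        n = min(n * 2, spec.max_samples)


def make_scenario_output(
    scenario: ScenarioDefinition,
    constants: ModelConstants,
    ranges: Sequence[ParameterRange],
    output_metric: str = "final_N",
    rtol: float = 1e-5,
) -> Callable[[np.ndarray], float]:
    """Build the model-evaluation function for a scenario.

    Environmental pools (P_0, D_0, pulsed additions) come from the
    scenario; the sampled vector supplies the microbial parameters named in
    ``ranges``.  Integration failures map to the collapse outcome (0).
    """
    names = [r.name for r in ranges]
    t_f_days = constants.t_f_days
    out_idx = {"final_N": "N", "final_P": "P"}[output_metric]

    def evaluate(x: np.ndarray) -> float:
        sample = dict(zip(names, x))
        n0 = sample.pop("N_0", constants.N_0)
        params = ModelParameters(
            mu_max=sample.get("mu_max", 0.0),
            m=sample.get("m", 0.0),
            gamma_cell=sample.get("gamma_cell", 0.0),
            alpha_D=sample.get("alpha_D", scenario.alpha_D),
            K_D=sample.get("K_D", constants.K_D),
            N_max=sample.get("N_max", constants.N_max),
            alpha_I=constants.alpha_I,
            I_xr=constants.I_xr,
        )
        initial = ModelState(N=n0, P=scenario.P_0, D=scenario.D_0, I=0.0)
        # physically the output cannot exceed these; a run that does has
        # numerically blown up and counts as a collapse outcome
        cap = params.N_max if out_idx == "N" else scenario.P_0 + scenario.P_in
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                traj = simulate(params, initial, t_f_days, rtol=rtol,
                                n_report=11)
        except RuntimeError:
            return 0.0
        value = float(getattr(traj, out_idx)[-1])
        if not math.isfinite(value) or value > 1.5 * cap:
            return 0.0
        return min(value, cap)

    return evaluate
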