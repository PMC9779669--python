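"""Greedy parameter-space sampling toward a target mean expression level.

The procedure explores the telegraph-model parameter space so that different
TF-binding scenarios can be compared at matched mean protein levels. Despite
the MCMC name it is a hill-climbing accept/reject walk, not a
likelihood-targeting sampler: a proposed parameter change is accepted iff it
moves the simulated population mean closer to the target (the midpoint of the
target window), and an accepted move is followed by another move of the same
parameter in the same direction. A rejected move is reverted; if it threw the
mean beyond the escape factor times the target range, the parameter to
perturb next is re-drawn at random. Chains stop on convergence (mean inside
the target window) or after a maximum number of iterations. A terminal run
is feasible only if its burst frequency lies inside an admissible window —
outside it the gene is effectively always-off or always-on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tfnoise.simulate import SimParams, SimResult, run_population

__all__ = [
    "PARAM_NAMES",
    "TARGET_WINDOWS",
    "MCMCConfig",
    "MCMCRun",
    "ParameterSearch",
    "initialize",
    "run_chain",
    "compare_noise",
]

PARAM_NAMES = ("lam_on", "lam_off", "beta_m", "beta_p", "alpha_m", "alpha_p")

#: The five canonical target mean-protein windows (molecules).
TARGET_WINDOWS = tuple(
    (1.0e6 + i * 1.0e5, 1.1e6 + i * 1.0e5) for i in range(5)
)

#: Canonical rates giving mean protein ~1e6 at burst frequency 0.5.
CANONICAL = {
    "lam_on": 1.0,
    "lam_off": 1.0,
    "beta_m": 100.0,
    "beta_p": 1.0e4,
    "alpha_m": 1.0,
    "alpha_p": 0.5,
}


def default_bounds(decades: float = 0.3) -> dict[str, tuple[float, float]]:
    """Per-parameter bounds: ±`decades` decades around the canonical values."""
    f = 10.0**decades
    return {k: (v / f, v * f) for k, v in CANONICAL.items()}


@dataclass
class MCMCConfig:
    """Configuration of the greedy parameter search."""

    target_window: tuple[float, float] = TARGET_WINDOWS[0]
    bounds: dict[str, tuple[float, float]] = field(default_factory=default_bounds)
    step_fraction: float = 0.10  # multiplicative step per move
    init_factor: float = 5.0  # admissible start: mean within init_factor× of target
    escape_factor: float = 2.0  # reject beyond escape_factor× window -> new parameter
    max_iterations: int = 50
    cells_per_eval: int = 1000
    n_replicates: int = 200
    burst_frequency_window: tuple[float, float] = (0.2, 0.8)
    max_init_draws: int = 400
    k_tfs: int = 2
    sim_template: SimParams = field(
        default_factory=lambda: SimParams(dt=0.05, total_time=30.0, burn_in=10.0)
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        low, high = self.target_window
        if not low < high:
            raise ValueError("target window must satisfy low < high")
        if self.init_factor <= 1 or self.escape_factor <= 1:
            raise ValueError("init and escape factors must be > 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            if not 0 < lo < hi:
                raise ValueError(f"invalid bounds for {name}")

    @property
    def target(self) -> float:
        """Target value: midpoint of the target window."""
        return 0.5 * (self.target_window[0] + self.target_window[1])


@dataclass
class MCMCRun:
    """One chain: trajectory, per-step decisions and terminal summary."""

    scenario: str
    target_window: tuple[float, float]
    steps: pd.DataFrame
    terminal_params: SimParams
    terminal_mean: float
    terminal_cv: float
    terminal_burst_frequency: float
    converged: bool
    feasible: bool
    n_iterations: int
    initial_mean: float


def _sim_params(config: MCMCConfig, scenario: str, values: dict[str, float]) -> SimParams:
    return replace(
        config.sim_template,
        scenario=scenario,
        k_tfs=1 if scenario == "single" else config.k_tfs,
        n_cells=config.cells_per_eval,
        seed=None,
        **values,
    )


def _evaluate(
    config: MCMCConfig, scenario: str, values: dict[str, float], rng: np.random.Generator
) -> SimResult:
    return run_population(_sim_params(config, scenario, values), rng)


def initialize(
    config: MCMCConfig, scenario: str, rng: np.random.Generator | None = None
) -> tuple[dict[str, float], float]:
    """Rejection-sample an admissible random start.

    Parameters are drawn log-uniformly within bounds until the simulated mean
    lies within `init_factor`× of the target (ratio in [1/f, f]); returns the
    parameter values and the achieved mean.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f = config.init_factor
    for _ in range(config.max_init_draws):
        values = {
            name: float(np.exp(rng.uniform(*np.log(config.bounds[name]))))
            for name in PARAM_NAMES
        }
        mean = _evaluate(config, scenario, values, rng).mean_protein
        if mean > 0 and 1.0 / f <= mean / config.target <= f:
            return values, mean
    raise RuntimeError(
        f"no admissible initialization within {config.max_init_draws} draws; "
        f"bounds {config.bounds} may be incompatible with target {config.target:.3g}"
    )


def run_chain(
    config: MCMCConfig, scenario: str, rng: np.random.Generator | None = None
) -> MCMCRun:
    """Run one greedy chain until convergence or the iteration cap."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    low, high = config.target_window
    target = config.target
    values, mean = initialize(config, scenario, rng)
    initial_mean = mean
    records: list[dict] = []
    converged = low <= mean <= high

    param = PARAM_NAMES[rng.integers(len(PARAM_NAMES))]
    direction = 1 if rng.random() < 0.5 else -1
    n_iter = 0
    while not converged and n_iter < config.max_iterations:
        n_iter += 1
        lo, hi = config.bounds[param]
        factor = (1.0 + config.step_fraction) ** direction
        proposed = values[param] * factor
        if not lo <= proposed <= hi:
            # at the bound in this direction: reject without evaluating
            records.append(
                {
                    "iteration": n_iter,
                    "parameter": param,
                    "direction": direction,
                    "accepted": False,
                    "evaluated": False,
                    "mean": np.nan,
                }
            )
            direction = 1 if rng.random() < 0.5 else -1
            param = PARAM_NAMES[rng.integers(len(PARAM_NAMES))]
            continue
        trial = dict(values)
        trial[param] = proposed
        trial_mean = _evaluate(config, scenario, trial, rng).mean_protein
        accepted = abs(trial_mean - target) < abs(mean - target)
        records.append(
            {
                "iteration": n_iter,
                "parameter": param,
                "direction": direction,
                "accepted": accepted,
                "evaluated": True,
                "mean": trial_mean,
            }
        )
        if accepted:
            values, mean = trial, trial_mean
            converged = low <= mean <= high
            # keep perturbing the same parameter in the same direction
        else:
            escaped = (
                trial_mean > config.escape_factor * high
                or trial_mean < low / config.escape_factor
            )
            if escaped:
                param = PARAM_NAMES[rng.integers(len(PARAM_NAMES))]
            direction = 1 if rng.random() < 0.5 else -1

    terminal = _evaluate(config, scenario, values, rng)
    bf = terminal.burst_frequency
    bf_lo, bf_hi = config.burst_frequency_window
    return MCMCRun(
        scenario=scenario,
        target_window=config.target_window,
        steps=pd.DataFrame(
            records,
            columns=["iteration", "parameter", "direction", "accepted", "evaluated", "mean"],
        ),
        terminal_params=_sim_params(config, scenario, values),
        terminal_mean=mean,
        terminal_cv=terminal.cv_protein,
        terminal_burst_frequency=bf,
        converged=converged,
        feasible=bool(bf_lo < bf < bf_hi),
        n_iterations=n_iter,
        initial_mean=initial_mean,
    )


def compare_noise(
    config: MCMCConfig,
    scenarios: Sequence[str] = ("single", "competitive", "cooperative"),
    n_replicates: int | None = None,
    seed: int | None = None,
) -> dict:
    """Replicate chains per scenario and compare terminal noise levels.

    Only converged and burst-frequency-feasible chains enter the comparison.
    Reports per-scenario replicate tables, median terminal CVs, and pairwise
    two-sided Mann-Whitney tests on the CV distributions.
    """
    n_replicates = config.n_replicates if n_replicates is None else n_replicates
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    tables: dict[str, pd.DataFrame] = {}
    for scen, child in zip(scenarios, ss.spawn(len(scenarios))):
        rows = []
        for rep_seed in child.spawn(n_replicates):
            run = run_chain(config, scen, np.random.default_rng(rep_seed))
            rows.append(
                {
                    "scenario": scen,
                    "target_low": config.target_window[0],
                    "target_high": config.target_window[1],
                    "converged": run.converged,
                    "feasible": run.feasible,
                    "mean": run.terminal_mean,
                    "cv": run.terminal_cv,
                    "burst_frequency": run.terminal_burst_frequency,
                    "n_iterations": run.n_iterations,
                }
            )
        tables[scen] = pd.DataFrame(rows)
    medians = {}
    usable = {}
    for scen, tab in tables.items():
        ok = tab[tab["converged"] & tab["feasible"]]
        usable[scen] = ok
        medians[scen] = float(ok["cv"].median()) if len(ok) else np.nan
    tests = {}
    names = list(scenarios)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = usable[names[i]]["cv"], usable[names[j]]["cv"]
            if len(a) >= 2 and len(b) >= 2:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            else:
                stat, p = np.nan, np.nan
            tests[(names[i], names[j])] = {"statistic": float(stat), "p_value": float(p)}
    return {"replicates": tables, "median_cv": medians, "tests": tests}


class ParameterSearch:
    """Object wrapper around the greedy chain for one configuration."""

    def __init__(self, config: MCMCConfig):
        self.config = config

    def run_chain(self, scenario: str, seed: int | None = None) -> MCMCRun:
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        return run_chain(self.config, scenario, rng)

    def compare(self, scenarios=("single", "competitive", "cooperative"), **kw) -> dict:
        return compare_noise(self.config, scenarios, **kw)
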