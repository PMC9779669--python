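"""Stochastic two-state (telegraph) simulation of TF-driven gene expression.

A promoter switches between a transcriptionally inactive (off) and active (on)
state with exponentially distributed waiting times: off-durations are drawn
``Exp(lam_on)`` and on-durations ``Exp(lam_off)``, so the long-run active
fraction is ``lam_on / (lam_on + lam_off)``. While active, mRNA is produced at
rate ``beta_m`` ("burst size"), translated at rate ``beta_p`` per mRNA, and
both species are removed at first-order rates ``alpha_m`` and ``alpha_p``.
Expression follows the forward-Euler updates

    mRNA[t+dt] = mRNA[t] + (beta_m_eff - alpha_m * mRNA[t]) * dt
    P[t+dt]    = P[t]    + (beta_p * mRNA[t] - alpha_p * P[t]) * dt

with ``beta_m_eff`` determined by the promoter state at time t.

Four TF-binding scenarios are supported:

single
    One telegraph process drives the gene.
independent
    Each of k TFs has its own telegraph process with the same rates; the gene
    is active when at least one TF is bound and the transcription rate is the
    sum of the bound TFs' individual rates (beta_m / k each, so the mean rate
    matches the single-TF case).
cooperative
    All k TFs must be bound simultaneously (all-or-none activation); each TF
    has the single-TF binding rates, so burst frequency — and hence mean
    expression — falls with k unless lam_off is recalibrated (`match_mean`).
competitive
    The TFs share one binding site: one telegraph process, and at each
    on-transition the bound TF is chosen uniformly at random; its
    strength multiplier scales beta_m for that on-interval. Multipliers
    average 1 so the mean transcription rate matches the single-TF case.

Binding/unbinding events occur at their exact exponential times; the promoter
state used for each Euler step is the state prevailing at the step's start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "CellTrajectory",
    "SimResult",
    "TelegraphSimulation",
    "simulate_state",
    "integrate_expression",
    "run_population",
    "run_population_ssa",
    "match_mean",
    "compare_scenarios",
    "cv_standard_error",
]

SCENARIOS = ("single", "independent", "cooperative", "competitive")

#: Sentinel used in event-time arrays for "never happens".
_NEVER = np.inf


def default_multipliers(k: int, spread: float = 0.3) -> np.ndarray:
    """Competitive strength multipliers: evenly spaced around 1.

    For k = 2 and the default spread this gives (1.3, 0.7). ``spread=0``
    means no variation in regulation strength (all multipliers 1).
    """
    if k == 1:
        return np.array([1.0])
    return np.linspace(1.0 + spread, 1.0 - spread, k)


@dataclass
class SimParams:
    """Rate constants and run configuration for one binding scenario.

    Rates are per unit time in arbitrary consistent units; `dt` must satisfy
    ``dt * alpha < 1`` for both removal rates (forward-Euler stability).
    """

    lam_on: float = 1.0
    lam_off: float = 1.0
    beta_m: float = 100.0
    beta_p: float = 100.0
    alpha_m: float = 1.0
    alpha_p: float = 0.5
    dt: float = 0.05
    total_time: float = 30.0
    n_cells: int = 10_000
    scenario: str = "single"
    k_tfs: int = 1
    multipliers: Sequence[float] | None = None
    hill_coefficient: float = 2.0
    burn_in: float | None = None
    swap_rate_convention: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("lam_on", "lam_off", "beta_m", "beta_p", "alpha_m", "alpha_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dt <= 0 or self.total_time <= 0:
            raise ValueError("dt and total_time must be positive")
        if self.dt * self.alpha_m > 1 or self.dt * self.alpha_p > 1:
            raise ValueError(
                "unstable forward-Euler step: require dt * alpha <= 1 "
                f"(dt*alpha_m={self.dt * self.alpha_m:.3g}, "
                f"dt*alpha_p={self.dt * self.alpha_p:.3g})"
            )
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.k_tfs < 1:
            raise ValueError("k_tfs must be >= 1")
        if self.k_tfs == 1 and self.scenario != "single":
            # one TF cannot cooperate or compete
            self.scenario = "single"
        if self.scenario == "single":
            self.k_tfs = 1
        if self.lam_on == 0 and self.lam_off == 0:
            warnings.warn("lam_on = lam_off = 0: promoter never switches", stacklevel=2)
        if self.scenario == "competitive":
            if self.multipliers is None:
                self.multipliers = tuple(default_multipliers(self.k_tfs))
            if len(self.multipliers) != self.k_tfs:
                raise ValueError("need one multiplier per competing TF")
            if abs(float(np.mean(self.multipliers)) - 1.0) > 1e-9:
                warnings.warn(
                    "competitive multipliers do not average 1; mean expression "
                    "will not match the single-TF scenario",
                    stacklevel=2,
                )

    @property
    def effective_burn_in(self) -> float:
        """Discarded initial transient: max(5/alpha_m, 5/alpha_p) unless set."""
        if self.burn_in is not None:
            return self.burn_in
        alphas = [a for a in (self.alpha_m, self.alpha_p) if a > 0]
        return max(5.0 / a for a in alphas) if alphas else 0.0

    @property
    def opening_rate(self) -> float:
        return self.lam_off if self.swap_rate_convention else self.lam_on

    @property
    def closing_rate(self) -> float:
        return self.lam_on if self.swap_rate_convention else self.lam_off

    @property
    def stationary_active_fraction(self) -> float:
        """Closed-form single-TF active fraction lam_on/(lam_on+lam_off)."""
        lo, lc = self.opening_rate, self.closing_rate
        if lo == 0 and lc == 0:
            return 0.0
        return lo / (lo + lc)


@dataclass
class CellTrajectory:
    """Time-resolved state of one simulated cell."""

    time: np.ndarray
    bound: np.ndarray  # (k_tfs, n_steps) boolean per-TF bound state
    active: np.ndarray  # (n_steps,) gene transcriptionally active
    rate: np.ndarray  # (n_steps,) transcription rate
    mrna: np.ndarray | None = None
    protein: np.ndarray | None = None


@dataclass
class SimResult:
    """Population summary pooled across cells and post-burn-in time points."""

    mean_protein: float
    cv_protein: float
    mean_mrna: float
    cv_mrna: float
    burst_frequency: float
    n_cells: int
    n_timepoints: int
    per_cell: pd.DataFrame = field(repr=False)
    params: SimParams = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "scenario": self.params.scenario if self.params else None,
            "k_tfs": self.params.k_tfs if self.params else None,
            "mean_protein": self.mean_protein,
            "cv_protein": self.cv_protein,
            "mean_mrna": self.mean_mrna,
            "cv_mrna": self.cv_mrna,
            "burst_frequency": self.burst_frequency,
            "n_cells": self.n_cells,
            "n_timepoints": self.n_timepoints,
        }


# ---------------------------------------------------------------------------
# event-time machinery (vectorised across cells)
# ---------------------------------------------------------------------------


def _event_times(
    rng: np.random.Generator,
    n_cells: int,
    opening_rate: float,
    closing_rate: float,
    total_time: float,
) -> np.ndarray:
    """Alternating switch times for cells starting in the off state.

    Row c holds the sorted times of state changes of cell c; entries beyond
    the horizon are +inf. Column 0 is the first off->on transition.
    """
    if opening_rate == 0:
        return np.full((n_cells, 1), _NEVER)
    mean_cycle = 1.0 / opening_rate + (1.0 / closing_rate if closing_rate > 0 else total_time)
    n_pairs = max(4, int(np.ceil(total_time / mean_cycle * 1.6 + 12)))
    while True:
        off_d = rng.exponential(1.0 / opening_rate, size=(n_cells, n_pairs))
        if closing_rate > 0:
            on_d = rng.exponential(1.0 / closing_rate, size=(n_cells, n_pairs))
        else:
            on_d = np.full((n_cells, n_pairs), _NEVER)
        dur = np.empty((n_cells, 2 * n_pairs))
        dur[:, 0::2] = off_d
        dur[:, 1::2] = on_d
        with np.errstate(invalid="ignore"):
            times = np.cumsum(dur, axis=1)
        if not np.isfinite(times[:, -1]).any() or times[:, -1].min() > total_time:
            return times
        n_pairs *= 2  # horizon not covered for some cell; redraw larger


def _event_counts_at(times: np.ndarray, grid: np.ndarray, horizon: float) -> np.ndarray:
    """Per-cell count of events occurring at or before each grid time.

    Vectorised row-wise searchsorted: rows are offset into a single sorted
    array. Returns an int array of shape (n_cells, len(grid)).
    """
    n_cells, m = times.shape
    big = 2.0 * horizon + 4.0
    clipped = np.minimum(times, big / 2.0)  # collapse inf; still > any grid time
    offsets = np.arange(n_cells)[:, None] * big
    flat = (clipped + offsets).ravel()
    queries = (grid[None, :] + offsets).ravel()
    idx = np.searchsorted(flat, queries, side="right").reshape(n_cells, len(grid))
    return idx - np.arange(n_cells)[:, None] * m


def _scenario_rates(
    params: SimParams, rng: np.random.Generator, n_cells: int, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell transcription rate and activity on the time grid.

    Returns (rate, active, bound) with shapes (n_cells, T), (n_cells, T) and
    (k_tfs, n_cells, T).
    """
    lo, lc = params.opening_rate, params.closing_rate
    horizon = params.total_time
    k = params.k_tfs
    if params.scenario in ("single", "competitive"):
        times = _event_times(rng, n_cells, lo, lc, horizon)
        counts = _event_counts_at(times, grid, horizon)
        bound1 = counts % 2 == 1
        if params.scenario == "single":
            rate = params.beta_m * bound1
        else:
            mult = np.asarray(params.multipliers, dtype=float)
            # the TF occupying each on-interval is chosen uniformly at random
            choice = rng.integers(0, k, size=(n_cells, times.shape[1] // 2 + 1))
            on_index = counts // 2
            chosen = np.take_along_axis(choice, np.minimum(on_index, choice.shape[1] - 1), axis=1)
            rate = np.where(bound1, mult[chosen] * params.beta_m, 0.0)
        return rate, bound1, bound1[None, :, :]

    # independent / cooperative: one telegraph process per TF, same rates
    bound = np.empty((k, n_cells, len(grid)), dtype=bool)
    for j in range(k):
        times = _event_times(rng, n_cells, lo, lc, horizon)
        counts = _event_counts_at(times, grid, horizon)
        bound[j] = counts % 2 == 1
    if params.scenario == "independent":
        active = bound.any(axis=0)
        rate = (params.beta_m / k) * bound.sum(axis=0)
    else:  # cooperative: all-or-none activation regardless of Hill coefficient
        active = bound.all(axis=0)
        rate = params.beta_m * active
    return rate, active, bound


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def simulate_state(params: SimParams, rng: np.random.Generator | None = None) -> CellTrajectory:
    """Simulate the promoter state trajectory of a single cell."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    grid = _time_grid(params)
    rate, active, bound = _scenario_rates(params, rng, 1, grid)
    return CellTrajectory(time=grid, bound=bound[:, 0, :], active=active[0], rate=rate[0])


def _time_grid(params: SimParams) -> np.ndarray:
    n_steps = int(round(params.total_time / params.dt))
    return np.arange(n_steps) * params.dt


def integrate_expression(
    state: CellTrajectory | np.ndarray, params: SimParams
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler mRNA and protein series from a transcription-rate series.

    `state` may be a CellTrajectory (filled in place) or a rate array of
    shape (n_steps,) or (n_cells, n_steps). Initial conditions are zero.
    """
    if isinstance(state, CellTrajectory):
        rate = state.rate[None, :]
    else:
        rate = np.atleast_2d(np.asarray(state, dtype=float))
    n_cells, n_steps = rate.shape
    mrna = np.zeros((n_cells, n_steps))
    prot = np.zeros((n_cells, n_steps))
    m = np.zeros(n_cells)
    p = np.zeros(n_cells)
    dt = params.dt
    for t in range(n_steps):
        mrna[:, t] = m
        prot[:, t] = p
        m = m + (rate[:, t] - params.alpha_m * m) * dt
        p = p + (params.beta_p * mrna[:, t] - params.alpha_p * p) * dt
    if isinstance(state, CellTrajectory):
        state.mrna = mrna[0]
        state.protein = prot[0]
        return mrna[0], prot[0]
    return np.squeeze(mrna), np.squeeze(prot)


def run_population(params: SimParams, rng: np.random.Generator | None = None) -> SimResult:
    """Simulate a cell population and pool protein statistics.

    Mean and CV are computed across all cells and all retained (post burn-in)
    time points; burst frequency is the retained-time fraction the gene spends
    transcriptionally active, averaged over cells.
    """
    if params.n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    grid = _time_grid(params)
    keep = grid >= params.effective_burn_in
    if not keep.any():
        raise ValueError("burn_in leaves no retained time points; increase total_time")
    rate, active, _ = _scenario_rates(params, rng, params.n_cells, grid)

    dt = params.dt
    m = np.zeros(params.n_cells)
    p = np.zeros(params.n_cells)
    s1p = np.zeros(params.n_cells)
    s2p = np.zeros(params.n_cells)
    s1m = np.zeros(params.n_cells)
    s2m = np.zeros(params.n_cells)
    n_kept = 0
    for t in range(len(grid)):
        if keep[t]:
            s1p += p
            s2p += p * p
            s1m += m
            s2m += m * m
            n_kept += 1
        m_next = m + (rate[:, t] - params.alpha_m * m) * dt
        p = p + (params.beta_p * m - params.alpha_p * p) * dt
        m = m_next

    active_frac = active[:, keep].mean(axis=1)
    per_cell = pd.DataFrame(
        {
            "protein_sum": s1p,
            "protein_sumsq": s2p,
            "mrna_sum": s1m,
            "mrna_sumsq": s2m,
            "n_timepoints": n_kept,
            "mean_protein": s1p / n_kept,
            "active_fraction": active_frac,
        }
    )
    mean_p = s1p.sum() / (params.n_cells * n_kept)
    var_p = s2p.sum() / (params.n_cells * n_kept) - mean_p**2
    mean_m = s1m.sum() / (params.n_cells * n_kept)
    var_m = s2m.sum() / (params.n_cells * n_kept) - mean_m**2
    if mean_p <= 0:
        warnings.warn("mean protein is 0; CV undefined", stacklevel=2)
        cv_p = np.nan
    else:
        cv_p = float(np.sqrt(max(var_p, 0.0)) / mean_p)
    cv_m = float(np.sqrt(max(var_m, 0.0)) / mean_m) if mean_m > 0 else np.nan
    return SimResult(
        mean_protein=float(mean_p),
        cv_protein=cv_p,
        mean_mrna=float(mean_m),
        cv_mrna=cv_m,
        burst_frequency=float(active_frac.mean()),
        n_cells=params.n_cells,
        n_timepoints=n_kept,
        per_cell=per_cell,
        params=params,
    )


def cv_standard_error(result: SimResult, n_groups: int = 10) -> float:
    """Monte-Carlo standard error of the pooled protein CV.

    Cells are split into `n_groups` disjoint groups; the CV is recomputed in
    each and the SE is the spread of group CVs divided by sqrt(n_groups).
    """
    pc = result.per_cell
    idx = np.array_split(np.arange(len(pc)), n_groups)
    cvs = []
    for ix in idx:
        n = pc["n_timepoints"].iloc[ix[0]] * len(ix)
        mu = pc["protein_sum"].iloc[ix].sum() / n
        var = pc["protein_sumsq"].iloc[ix].sum() / n - mu**2
        cvs.append(np.sqrt(max(var, 0.0)) / mu)
    return float(np.std(cvs, ddof=1) / np.sqrt(n_groups))


def match_mean(
    params: SimParams,
    reference_mean: float,
    tolerance: float = 0.02,
    max_iter: int = 40,
    rng: np.random.Generator | None = None,
) -> tuple[SimParams, float]:
    """Calibrate lam_off so the population mean matches `reference_mean`.

    Mean protein increases monotonically as lam_off decreases (on-states are
    prolonged), so a bisection on log(lam_off) converges. Returns the
    calibrated parameters and the achieved mean.
    """
    if reference_mean <= 0:
        raise ValueError("reference_mean must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    seeds = np.random.SeedSequence(entropy=int(rng.integers(2**31))).spawn(max_iter + 2)

    def mean_at(lam_off: float, seed_idx: int) -> float:
        p = replace(params, lam_off=lam_off, seed=None)
        res = run_population(p, np.random.default_rng(seeds[seed_idx]))
        return res.mean_protein

    hi = params.lam_off
    m_hi = mean_at(hi, 0)
    if abs(m_hi - reference_mean) / reference_mean <= tolerance:
        return replace(params, lam_off=hi), m_hi
    if m_hi > reference_mean:
        raise ValueError(
            "mean at current lam_off already exceeds reference; lam_off can only "
            "be reduced (which raises the mean)"
        )
    lo = hi
    m_lo = m_hi
    for i in range(12):
        lo /= 8.0
        m_lo = mean_at(lo, 1)
        if m_lo >= reference_mean:
            break
    else:
        raise ValueError(
            f"target mean {reference_mean:.3g} unreachable: even lam_off={lo:.3g} "
            f"gives mean {m_lo:.3g}"
        )
    achieved = m_lo
    lam = lo
    for i in range(max_iter):
        lam = np.sqrt(lo * hi)
        achieved = mean_at(lam, i + 2)
        if abs(achieved - reference_mean) / reference_mean <= tolerance:
            break
        if achieved > reference_mean:
            lo = lam
        else:
            hi = lam
    return replace(params, lam_off=float(lam)), float(achieved)


def compare_scenarios(
    base: SimParams,
    scenarios: Sequence[str] = SCENARIOS,
    k_tfs: int = 2,
    matched: bool = True,
    match_tolerance: float = 0.03,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mathematically controlled comparison of binding scenarios.

    All scenarios share the base rates; only the binding process differs.
    TF concentrations follow the matched conventions: each cooperative TF
    binds at the single-TF rate, while the competing TFs' combined
    concentration equals the single TF's (one shared telegraph process).
    With ``matched=True`` the cooperative lam_off is recalibrated so its mean
    matches the single-TF mean.
    """
    seed = base.seed if seed is None else seed
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    child = ss.spawn(len(scenarios) + 1)
    ref = run_population(
        replace(base, scenario="single", k_tfs=1), np.random.default_rng(child[-1])
    )
    rows = []
    for i, scen in enumerate(scenarios):
        rng = np.random.default_rng(child[i])
        p = replace(base, scenario=scen, k_tfs=1 if scen == "single" else k_tfs)
        if scen == "cooperative" and matched:
            p, _ = match_mean(p, ref.mean_protein, tolerance=match_tolerance, rng=rng)
        res = run_population(p, rng)
        row = res.to_dict()
        row["cv_se"] = cv_standard_error(res)
        rows.append(row)
    return pd.DataFrame(rows)


def run_population_ssa(
    params: SimParams, rng: np.random.Generator | None = None
) -> SimResult:
    """Exact stochastic simulation with integer copy numbers (cross-check).

    A Gillespie realization of the single-TF telegraph system with discrete
    mRNA/protein birth-death events. Unlike the default integrator — which
    propagates concentrations deterministically between switching events, so
    all noise comes from promoter switching — this engine also carries the
    intrinsic birth-death (shot) noise, so its CV is an upper envelope of
    the default engine's. Means agree. Intended as a validation tool, not
    the default; single-TF scenario only, and much slower.
    """
    if params.scenario != "single":
        raise NotImplementedError("SSA cross-check engine supports the single-TF scenario")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    grid = _time_grid(params)
    keep = grid >= params.effective_burn_in
    n_kept = int(keep.sum())
    s1p = s2p = s1m = s2m = 0.0
    active_time = 0.0
    per_cell_rows = []
    lo, lc = params.opening_rate, params.closing_rate
    for _ in range(params.n_cells):
        t, m, p, on = 0.0, 0, 0, False
        gi = 0
        c1p = c2p = c1m = c2m = 0.0
        c_active = 0
        uniforms = rng.random(65536)
        ui = 0
        while gi < len(grid):
            if ui >= len(uniforms) - 2:
                uniforms = rng.random(65536)
                ui = 0
            r_switch = lc if on else lo
            r_mb = params.beta_m if on else 0.0
            r_md = params.alpha_m * m
            r_pb = params.beta_p * m
            r_pd = params.alpha_p * p
            total = r_switch + r_mb + r_md + r_pb + r_pd
            dt_next = -np.log(uniforms[ui]) / total if total > 0 else np.inf
            ui += 1
            # record grid points passed before the next event fires
            while gi < len(grid) and grid[gi] < t + dt_next:
                if keep[gi]:
                    c1p += p
                    c2p += p * p
                    c1m += m
                    c2m += m * m
                    c_active += on
                gi += 1
            if not np.isfinite(dt_next):
                break
            t += dt_next
            u = uniforms[ui] * total
            ui += 1
            if u < r_switch:
                on = not on
            elif u < r_switch + r_mb:
                m += 1
            elif u < r_switch + r_mb + r_md:
                m -= 1
            elif u < r_switch + r_mb + r_md + r_pb:
                p += 1
            else:
                p -= 1
        s1p += c1p
        s2p += c2p
        s1m += c1m
        s2m += c2m
        active_time += c_active / n_kept
        per_cell_rows.append(
            {
                "protein_sum": c1p,
                "protein_sumsq": c2p,
                "mrna_sum": c1m,
                "mrna_sumsq": c2m,
                "n_timepoints": n_kept,
                "mean_protein": c1p / n_kept,
                "active_fraction": c_active / n_kept,
            }
        )
    n_total = params.n_cells * n_kept
    mean_p = s1p / n_total
    var_p = s2p / n_total - mean_p**2
    mean_m = s1m / n_total
    var_m = s2m / n_total - mean_m**2
    return SimResult(
        mean_protein=float(mean_p),
        cv_protein=float(np.sqrt(max(var_p, 0.0)) / mean_p) if mean_p > 0 else np.nan,
        mean_mrna=float(mean_m),
        cv_mrna=float(np.sqrt(max(var_m, 0.0)) / mean_m) if mean_m > 0 else np.nan,
        burst_frequency=float(active_time / params.n_cells),
        n_cells=params.n_cells,
        n_timepoints=n_kept,
        per_cell=pd.DataFrame(per_cell_rows),
        params=params,
    )


class TelegraphSimulation:
    """Object-style wrapper: configure once, then run populations.

    Examples
    --------
    >>> sim = TelegraphSimulation(SimParams(scenario="single", n_cells=500, seed=0))
    >>> res = sim.run()
    >>> 0 < res.burst_frequency < 1
    True
    """

    def __init__(self, params: SimParams):
        self.params = params

    def run(self) -> SimResult:
        return run_population(self.params)

    def sample_trajectory(self, seed: int | None = None) -> CellTrajectory:
        rng = np.random.default_rng(self.params.seed if seed is None else seed)
        traj = simulate_state(self.params, rng)
        integrate_expression(traj, self.params)
        return traj

    def matched_to(self, reference_mean: float, tolerance: float = 0.02) -> "TelegraphSimulation":
        params, _ = match_mean(self.params, reference_mean, tolerance)
        return TelegraphSimulation(params)
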