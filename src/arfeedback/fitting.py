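"""Parameter estimation for the feedback models.

Fitting scores a candidate parameter set by simulating the control and
PARP7-inhibitor conditions side by side, normalizing the simulated target
transcript to a maximum of 100, and summing squared errors against the
observed composite profile in each condition; the two SSE scores are
added.  Estimation is two-stage: a Monte Carlo screen draws parameter
sets log-uniformly within bounds and keeps the best scorers, then each
survivor seeds a Metropolis–Hastings chain with multiplicative Gaussian
proposals and a fixed-temperature Boltzmann acceptance rule on the SSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _ode, _search
from .models import (
    ConfigurationError,
    InitialConditions,
    ModelArchitecture,
    PARAM_NAMES,
    ParameterSet,
    SimulationGrid,
    Trajectory,
)

__all__ = [
    "ObservedProfile",
    "FitResult",
    "SearchConfig",
    "SearchFailure",
    "EstimationResult",
    "compute_sse",
    "monte_carlo_search",
    "metropolis_refine",
    "metropolis_chain",
    "estimate_parameters",
    "DEFAULT_BOUNDS",
]

_FAST = PARAM_NAMES.index("k_deg_p7_fast")
_SLOW = PARAM_NAMES.index("k_deg_p7_slow")


class SearchFailure(RuntimeError):
    """Every candidate parameter set failed to simulate."""


#: Default sampling bounds, set by dimensional analysis rather than one
#: global range: second-order rates act per molecule (characteristic
#: fluxes k*N with N ~ 660 molecules), first-order rates are per hour
#: against a 22-hour observation window, and K_stab is a molecule count
#: on the scale of the AR pool.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    # second order (per molecule per hour)
    "k_rep_ar": (1e-4, 1e0),
    "k_on_AR": (1e-4, 1e0),
    "k_on_ADP": (1e-4, 1e0),
    "k_cat_adp": (1e-4, 1e0),
    # zeroth/first order (per hour)
    "k_trl_ar": (1e-2, 1e2),
    "k_tx_ar": (1e-2, 1e2),
    "k_deg_arm": (1e-2, 1e2),
    "k_off_AR": (1e-2, 1e2),
    "k_off_ADP": (1e-2, 1e2),
    "k_deg_adp": (1e-2, 1e2),
    "k_tx_p7": (1e-2, 1e2),
    "k_deg_p7m": (1e-2, 1e2),
    "k_trl_p7": (1e-2, 1e2),
    "k_deg_p7_fast": (1e-2, 1e2),
    "k_deg_p7_slow": (1e-2, 1e2),
    "k_tx_target": (1e-2, 1e2),
    "k_deg_target": (1e-2, 1e2),
    # half-saturation constant (molecules)
    "K_stab": (1e0, 1e3),
}


@dataclass(frozen=True)
class ObservedProfile:
    """Paired control/inhibitor composite transcript time course.

    Values are normalized (maximum 100 per condition).  The default
    source genes name the composite of PARP7, F3, and ERRFI1.
    """

    times: np.ndarray
    control_values: np.ndarray
    inhibitor_values: np.ndarray
    source_genes: tuple[str, ...] = ("PARP7", "F3", "ERRFI1")

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "control_values",
                           np.asarray(self.control_values, dtype=float))
        object.__setattr__(self, "inhibitor_values",
                           np.asarray(self.inhibitor_values, dtype=float))
        t = self.times
        if t.ndim != 1 or t.size == 0:
            raise ConfigurationError("times must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("times must be strictly increasing")
        for name in ("control_values", "inhibitor_values"):
            v = getattr(self, name)
            if v.shape != t.shape:
                raise ConfigurationError(f"{name} length must match times")
            if np.any(~np.isfinite(v)) or v.min() < 0 or v.max() > 100 + 1e-9:
                raise ConfigurationError(f"{name} must lie in [0, 100]")

    @classmethod
    def from_csv(cls, path, source_genes=("PARP7", "F3", "ERRFI1")):
        """Read a long-format CSV with columns time_h, value, condition."""
        df = pd.read_csv(path)
        required = {"time_h", "value", "condition"}
        if not required.issubset(df.columns):
            raise ConfigurationError(
                f"observed CSV needs columns {sorted(required)}")
        pieces = {}
        for cond in ("control", "inhibitor"):
            sub = df[df["condition"] == cond].sort_values("time_h")
            if sub.empty:
                raise ConfigurationError(f"no rows with condition={cond!r}")
            pieces[cond] = sub
        t = pieces["control"]["time_h"].to_numpy()
        if not np.array_equal(t, pieces["inhibitor"]["time_h"].to_numpy()):
            raise ConfigurationError(
                "control and inhibitor conditions must share time points")
        return cls(times=t,
                   control_values=pieces["control"]["value"].to_numpy(),
                   inhibitor_values=pieces["inhibitor"]["value"].to_numpy(),
                   source_genes=tuple(source_genes))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, vals in (("control", self.control_values),
                           ("inhibitor", self.inhibitor_values)):
            rows.append(pd.DataFrame(
                {"time_h": self.times, "value": vals, "condition": cond}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def n_points(self) -> int:
        """Fitted data points across both conditions."""
        return 2 * self.times.size


@dataclass(frozen=True)
class FitResult:
    params: ParameterSet
    sse_control: float
    sse_inhibitor: float
    sse_total: float
    rank: int

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "sse_control": self.sse_control,
            "sse_inhibitor": self.sse_inhibitor,
            "sse_total": self.sse_total,
            "params": self.params.to_dict(),
        }


@dataclass(frozen=True)
class SearchConfig:
    """Settings for the two-stage search.

    Defaults follow the full-scale estimation protocol: a 100,000-draw
    Monte Carlo screen, the top 100 sets retained, and 5,000 refinement
    steps per set (600,000 paired simulations in total).
    :meth:`reduced` gives a desk-scale configuration.

    ``bounds`` is either a global ``(low, high)`` pair or a mapping from
    parameter name to a pair (default: :data:`DEFAULT_BOUNDS`); sampling
    is log-uniform by default (rate constants span orders of magnitude),
    switchable to linear-uniform.  ``temperature`` controls Boltzmann
    acceptance of worsening moves: the default ``0`` is the greedy limit
    (accept only improvements, the effective choice for short chains);
    ``None`` sets each chain's temperature to 10% of its starting SSE.
    """

    n_mc: int = 100_000
    top_k: int = 100
    n_mh: int = 5_000
    bounds: tuple[float, float] | Mapping[str, tuple[float, float]] | None = None
    sampling: str = "log-uniform"
    proposal_cv: float = 0.05
    temperature: float | None = 0.0
    seed: int = 0
    sim_rtol: float = 1e-3
    sim_atol: float = 1e-6
    sim_max_steps: int = 10_000

    def __post_init__(self) -> None:
        if self.n_mc < 1:
            raise ConfigurationError("n_mc must be >= 1")
        if not 1 <= self.top_k <= self.n_mc:
            raise ConfigurationError("top_k must be in [1, n_mc]")
        if self.n_mh < 0:
            raise ConfigurationError("n_mh must be >= 0")
        if self.sampling not in ("log-uniform", "uniform"):
            raise ConfigurationError("sampling must be 'log-uniform' or 'uniform'")

    @classmethod
    def reduced(cls, seed: int = 0, **kwargs) -> "SearchConfig":
        """Desk-scale configuration (5,000 draws, top 20, 500 MH steps)."""
        kwargs.setdefault("n_mc", 5_000)
        kwargs.setdefault("top_k", 20)
        kwargs.setdefault("n_mh", 500)
        return cls(seed=seed, **kwargs)

    @property
    def total_simulations(self) -> int:
        """Paired simulations the two-stage search performs."""
        return self.n_mc + self.top_k * self.n_mh

    def bounds_array(self, arch: ModelArchitecture) -> np.ndarray:
        """(18, 2) low/high array; inactive parameters get (0, 0)."""
        active = set(arch.active_parameters())
        bounds = DEFAULT_BOUNDS if self.bounds is None else self.bounds
        out = np.zeros((len(PARAM_NAMES), 2))
        for i, name in enumerate(PARAM_NAMES):
            if name not in active:
                continue
            if isinstance(bounds, Mapping):
                if name not in bounds:
                    raise ConfigurationError(
                        f"bounds missing for active parameter {name}")
                lo, hi = bounds[name]
            else:
                lo, hi = bounds
            if not (0 <= lo < hi):
                raise ConfigurationError(f"invalid bounds for {name}: ({lo}, {hi})")
            if self.sampling == "log-uniform" and lo <= 0:
                raise ConfigurationError(
                    f"log-uniform sampling needs low bound > 0 for {name}")
            out[i] = (lo, hi)
        return out


@dataclass(frozen=True)
class EstimationResult:
    fits: tuple[FitResult, ...]
    n_simulations: int

    @property
    def best(self) -> FitResult:
        return self.fits[0]


def compute_sse(
    pair: tuple[Trajectory | None, Trajectory | None],
    observed: ObservedProfile,
) -> tuple[float, float, float]:
    """SSE of a paired simulation against the observed profile.

    The simulated normalized target is linearly interpolated to the
    observed times; squared errors are summed per condition and the two
    scores added.  A missing (failed) member yields ``(inf, inf, inf)``.
    """
    control, inhibitor = pair
    if control is None or inhibitor is None:
        return (math.inf, math.inf, math.inf)
    t = observed.times
    for traj in (control, inhibitor):
        if t[0] < traj.times[0] - 1e-12 or t[-1] > traj.times[-1] + 1e-12:
            raise ConfigurationError("observed times outside trajectory span")
    sim_c = np.interp(t, control.times, control.target_norm)
    sim_i = np.interp(t, inhibitor.times, inhibitor.target_norm)
    sse_c = float(np.sum((sim_c - observed.control_values) ** 2))
    sse_i = float(np.sum((sim_i - observed.inhibitor_values) ** 2))
    return (sse_c, sse_i, sse_c + sse_i)


def _default_grid(observed: ObservedProfile) -> SimulationGrid:
    return SimulationGrid.hourly(math.ceil(observed.times[-1]))


def _sample_matrix(arch: ModelArchitecture, config: SearchConfig,
                   rng: np.random.Generator, n: int) -> np.ndarray:
    bounds = config.bounds_array(arch)
    lo, hi = bounds[:, 0], bounds[:, 1]
    active = hi > lo
    P = np.zeros((n, len(PARAM_NAMES)))
    if config.sampling == "log-uniform":
        P[:, active] = np.exp(rng.uniform(
            np.log(lo[active]), np.log(hi[active]), size=(n, active.sum())))
    else:
        P[:, active] = rng.uniform(lo[active], hi[active],
                                   size=(n, active.sum()))
    # the fast PARP7 decay rate is the larger of the sampled pair
    fast = np.maximum(P[:, _FAST], P[:, _SLOW])
    slow = np.minimum(P[:, _FAST], P[:, _SLOW])
    P[:, _FAST], P[:, _SLOW] = fast, slow
    return P


def _rank_results(P: np.ndarray, sse: np.ndarray, top_k: int) -> list[FitResult]:
    total = sse[:, 0] + sse[:, 1]
    order = np.argsort(total, kind="stable")  # +inf sorts last
    results = []
    for rank, idx in enumerate(order[:top_k], start=1):
        results.append(FitResult(
            params=ParameterSet.from_vector(P[idx]),
            sse_control=float(sse[idx, 0]),
            sse_inhibitor=float(sse[idx, 1]),
            sse_total=float(total[idx]),
            rank=rank))
    return results


def monte_carlo_search(
    arch: ModelArchitecture | str,
    observed: ObservedProfile,
    init: InitialConditions | None = None,
    grid: SimulationGrid | None = None,
    config: SearchConfig | None = None,
) -> list[FitResult]:
    """Screen ``config.n_mc`` random parameter sets, return the top
    ``config.top_k`` ranked by total SSE (failed simulations score +inf
    and rank last)."""
    arch = ModelArchitecture.coerce(arch)
    init = init or InitialConditions()
    config = config or SearchConfig()
    grid = grid or _default_grid(observed)
    rng = np.random.default_rng(config.seed)
    P = _sample_matrix(arch, config, rng, config.n_mc)
    sse = _search.score_batch(
        arch.code, P, init.state_vector(arch), grid.times,
        observed.times, observed.control_values, observed.inhibitor_values,
        config.sim_rtol, config.sim_atol, config.sim_max_steps)
    if not np.any(np.isfinite(sse[:, 0] + sse[:, 1])):
        raise SearchFailure("all Monte Carlo candidates failed to simulate")
    return _rank_results(P, sse, config.top_k)


def _chain_seed(seed: int, chain_index: int) -> int:
    ss = np.random.SeedSequence([int(seed), int(chain_index)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def metropolis_refine(
    arch: ModelArchitecture | str,
    observed: ObservedProfile,
    start: ParameterSet,
    init: InitialConditions | None = None,
    grid: SimulationGrid | None = None,
    config: SearchConfig | None = None,
    start_sse: tuple[float, float] | None = None,
    seed: int | None = None,
    return_chain: bool = True,
) -> tuple[list[tuple[ParameterSet, float]], FitResult]:
    """Refine one parameter set with a Metropolis–Hastings chain.

    Gaussian proposals scale with the current value (``proposal_cv``);
    acceptance is ``min(1, exp((SSE_cur - SSE_prop)/temperature))``.  The
    returned best is the lowest-SSE state visited, so refinement never
    worsens the starting score.  ``start_sse`` may pass a pre-computed
    (control, inhibitor) score to avoid re-simulation.
    """
    arch = ModelArchitecture.coerce(arch)
    init = init or InitialConditions()
    config = config or SearchConfig()
    grid = grid or _default_grid(observed)
    y0 = init.state_vector(arch)

    if start_sse is None:
        sc, si = _search._score_one(
            arch.code, start.to_vector(), y0, grid.times,
            observed.times, observed.control_values,
            observed.inhibitor_values,
            config.sim_rtol, config.sim_atol, config.sim_max_steps)
    else:
        sc, si = start_sse
    if not math.isfinite(sc + si):
        raise ConfigurationError("start parameter set must have finite SSE")

    temperature = config.temperature
    if temperature is None:
        temperature = 0.1 * (sc + si)

    active = np.array(
        [hi > lo for lo, hi in config.bounds_array(arch)], dtype=np.bool_)
    chain_seed = _chain_seed(config.seed, 0) if seed is None else int(seed)

    chain_p, chain_s, best_idx = _search.mh_chain(
        arch.code, start.to_vector(), active, y0, grid.times,
        observed.times, observed.control_values, observed.inhibitor_values,
        int(config.n_mh), float(config.proposal_cv), float(temperature),
        float(sc), float(si), chain_seed,
        config.sim_rtol, config.sim_atol, config.sim_max_steps)

    best = FitResult(
        params=ParameterSet.from_vector(chain_p[best_idx]),
        sse_control=float(chain_s[best_idx, 0]),
        sse_inhibitor=float(chain_s[best_idx, 1]),
        sse_total=float(chain_s[best_idx, 0] + chain_s[best_idx, 1]),
        rank=1)

    chain: list[tuple[ParameterSet, float]] = []
    if return_chain:
        for i in range(chain_p.shape[0]):
            chain.append((ParameterSet.from_vector(chain_p[i]),
                          float(chain_s[i, 0] + chain_s[i, 1])))
    return chain, best


def metropolis_chain(
    objective,
    start: np.ndarray,
    n_steps: int,
    proposal_cv: float = 0.05,
    temperature: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Generic Metropolis–Hastings descent on an arbitrary objective.

    Reference form of the refinement rule used by :func:`metropolis_refine`
    for any callable ``objective(theta) -> score``: Gaussian proposals with
    standard deviation ``proposal_cv * |current|`` per coordinate (negative
    draws re-drawn), acceptance ``min(1, exp((cur - prop)/temperature))``,
    greedy when ``temperature <= 0``.  Returns ``(chain, scores)`` with
    ``n_steps + 1`` rows.  Useful for studying the sampler on surrogate
    objectives without the ODE solver in the loop.
    """
    rng = np.random.default_rng(seed)
    theta = np.atleast_1d(np.asarray(start, dtype=float)).copy()
    cur = float(objective(theta))
    chain = np.empty((n_steps + 1, theta.size))
    scores = np.empty(n_steps + 1)
    chain[0] = theta
    scores[0] = cur
    for step in range(1, n_steps + 1):
        prop = np.empty_like(theta)
        for j in range(theta.size):
            sd = proposal_cv * abs(theta[j])
            v = theta[j] + sd * rng.standard_normal()
            while v < 0:
                v = theta[j] + sd * rng.standard_normal()
            prop[j] = v
        s = float(objective(prop))
        accept = s <= cur or (
            temperature > 0
            and rng.random() < math.exp((cur - s) / temperature))
        if accept:
            theta, cur = prop, s
        chain[step] = theta
        scores[step] = cur
    return chain, scores


def estimate_parameters(
    arch: ModelArchitecture | str,
    observed: ObservedProfile,
    init: InitialConditions | None = None,
    grid: SimulationGrid | None = None,
    config: SearchConfig | None = None,
) -> EstimationResult:
    """Two-stage estimation: Monte Carlo screen, then Metropolis–Hastings
    refinement of each retained set.

    Chain seeds derive deterministically from ``config.seed`` and the
    chain index; refined results are re-ranked by total SSE.  The total
    number of paired simulations is ``n_mc + top_k * n_mh`` (Monte Carlo
    scores are reused as chain starting scores).
    """
    arch = ModelArchitecture.coerce(arch)
    init = init or InitialConditions()
    config = config or SearchConfig()
    grid = grid or _default_grid(observed)

    screened = monte_carlo_search(arch, observed, init, grid, config)
    n_sim = config.n_mc

    refined: list[FitResult] = []
    for chain_index, fit in enumerate(screened):
        if not math.isfinite(fit.sse_total):
            refined.append(fit)  # unrefinable; keeps its +inf score
            continue
        _, best = metropolis_refine(
            arch, observed, fit.params, init, grid, config,
            start_sse=(fit.sse_control, fit.sse_inhibitor),
            seed=_chain_seed(config.seed, chain_index),
            return_chain=False)
        n_sim += config.n_mh
        refined.append(best)

    order = np.argsort([f.sse_total for f in refined], kind="stable")
    fits = tuple(
        FitResult(params=refined[i].params,
                  sse_control=refined[i].sse_control,
                  sse_inhibitor=refined[i].sse_inhibitor,
                  sse_total=refined[i].sse_total,
                  rank=rank)
        for rank, i in enumerate(order, start=1))
    return EstimationResult(fits=fits, n_simulations=n_sim)
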