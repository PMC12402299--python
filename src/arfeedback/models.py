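"""Mass-action ODE models of the AR–PARP7 negative feedback loop.

The androgen receptor (AR) induces the mono-ADP-ribosyltransferase PARP7,
which marks AR for proteasomal degradation; the loop limits AR
transcriptional output after a multi-hour delay.  Three competing
architectures are provided:

``simple``
    No explicit promoter species; free AR drives transcription directly
    and is ADP-ribosylated wherever it is.
``chromatin``
    AR must bind a promoter to transcribe, and PARP7 modifies only
    promoter-bound AR.
``nucleoplasm``
    AR must bind a promoter to transcribe, and PARP7 modifies only free
    (nucleoplasmic) AR.

In every architecture all AR is ligand-bound, unmodified AR is not
degraded, AR represses its own transcript by mass action, ADP-ribosylated
AR is degraded (free pool only), and PARP7 protein decays at a fast rate
that AR shifts toward a slow rate.  A PARP7-inhibitor condition is the
same system with the catalytic ADP-ribosylation rate forced to zero.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _ode

__all__ = [
    "ModelArchitecture",
    "ParameterSet",
    "InitialConditions",
    "SimulationGrid",
    "Trajectory",
    "InvalidSimulation",
    "NormalizationError",
    "ConfigurationError",
    "STATE_NAMES",
    "build_rhs",
    "simulate",
    "simulate_paired",
    "normalize_to_max100",
    "ratio_scan",
]

STATE_NAMES = (
    "mRNA_AR", "AR_free", "AR_adp_free", "P_free", "C_AR", "C_ADP",
    "mRNA_P7", "P7", "T",
)

#: parameter order shared with the compiled kernels
PARAM_NAMES = (
    "k_trl_ar", "k_tx_ar", "k_rep_ar", "k_deg_arm",
    "k_on_AR", "k_off_AR", "k_on_ADP", "k_off_ADP",
    "k_cat_adp", "k_deg_adp", "k_tx_p7", "k_deg_p7m",
    "k_trl_p7", "k_deg_p7_fast", "k_deg_p7_slow", "K_stab",
    "k_tx_target", "k_deg_target",
)

#: promoter binding/unbinding rates are meaningless without promoter species
BINDING_PARAMS = ("k_on_AR", "k_off_AR", "k_on_ADP", "k_off_ADP")


class ConfigurationError(ValueError):
    """Invalid model, parameter, or grid configuration."""


class InvalidSimulation(RuntimeError):
    """The integrator failed or produced a non-physical state."""


class NormalizationError(ValueError):
    """A series cannot be normalized to a maximum of 100."""


class ModelArchitecture(str, enum.Enum):
    SIMPLE = "simple"
    CHROMATIN = "chromatin"
    NUCLEOPLASM = "nucleoplasm"

    @classmethod
    def coerce(cls, value: "ModelArchitecture | str") -> "ModelArchitecture":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ConfigurationError(
                f"unknown architecture {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None

    @property
    def code(self) -> int:
        return {"simple": 0, "chromatin": 1, "nucleoplasm": 2}[self.value]

    @property
    def has_promoter(self) -> bool:
        return self is not ModelArchitecture.SIMPLE

    def active_parameters(self) -> tuple[str, ...]:
        """Names of the rate constants this architecture actually uses."""
        if self.has_promoter:
            return PARAM_NAMES
        return tuple(n for n in PARAM_NAMES if n not in BINDING_PARAMS)

    @property
    def n_params(self) -> int:
        return len(self.active_parameters())


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants of the feedback model (units: per hour; K_stab in
    molecules).

    All rates must be non-negative and the fast PARP7 decay rate must not
    be below the slow one.  For the ``simple`` architecture the four
    promoter binding rates are inactive; :meth:`active_dict` reports them
    as such.
    """

    k_trl_ar: float = 0.0
    k_tx_ar: float = 0.0
    k_rep_ar: float = 0.0
    k_deg_arm: float = 0.0
    k_on_AR: float = 0.0
    k_off_AR: float = 0.0
    k_on_ADP: float = 0.0
    k_off_ADP: float = 0.0
    k_cat_adp: float = 0.0
    k_deg_adp: float = 0.0
    k_tx_p7: float = 0.0
    k_deg_p7m: float = 0.0
    k_trl_p7: float = 0.0
    k_deg_p7_fast: float = 0.0
    k_deg_p7_slow: float = 0.0
    K_stab: float = 1.0
    k_tx_target: float = 0.0
    k_deg_target: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(
                    f"parameter {f.name} must be finite and >= 0, got {v}")
        if self.k_deg_p7_fast < self.k_deg_p7_slow:
            raise ConfigurationError(
                "k_deg_p7_fast must be >= k_deg_p7_slow "
                f"({self.k_deg_p7_fast} < {self.k_deg_p7_slow})")

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "ParameterSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_NAMES),):
            raise ConfigurationError(
                f"expected {len(PARAM_NAMES)} parameters, got {vec.shape}")
        return cls(**dict(zip(PARAM_NAMES, vec.tolist())))

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "ParameterSet":
        unknown = set(data) - set(PARAM_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def active_dict(self, arch: ModelArchitecture | str) -> dict[str, float | None]:
        """Parameter mapping with inactive entries reported as ``None``."""
        arch = ModelArchitecture.coerce(arch)
        active = set(arch.active_parameters())
        return {n: (float(getattr(self, n)) if n in active else None)
                for n in PARAM_NAMES}

    def replace(self, **kwargs: float) -> "ParameterSet":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InitialConditions:
    """Initial molecule counts; every species other than AR and promoters
    starts at zero.

    The defaults encode roughly 20,000 AR molecules per cell distributed
    over about 3,050 androgen-responsive promoters, scaled to 660 AR and
    100 promoters (ratio 6.6).
    """

    AR0: float = 660.0
    P0: float = 100.0

    def __post_init__(self) -> None:
        if self.AR0 < 0 or self.P0 < 0:
            raise ConfigurationError("initial counts must be >= 0")

    @property
    def ratio(self) -> float:
        return self.AR0 / self.P0

    def state_vector(self, arch: ModelArchitecture | str) -> np.ndarray:
        arch = ModelArchitecture.coerce(arch)
        y0 = np.zeros(_ode.N_STATE)
        y0[1] = self.AR0
        if arch.has_promoter:
            y0[3] = self.P0
        return y0

    @classmethod
    def from_json(cls, path) -> "InitialConditions":
        with open(path) as fh:
            data = json.load(fh)
        unknown = set(data) - {"AR0", "P0"}
        if unknown:
            raise ConfigurationError(f"unknown initial-condition keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class SimulationGrid:
    """Reporting grid: ``n_points`` intervals of ``dt_report`` hours.

    The default (2200 intervals of 0.01 h) reports 100 points per
    simulated hour over a 22-hour time course; the initial state at
    ``t_start`` is reported as well.
    """

    t_start: float = 0.0
    n_points: int = 2200
    dt_report: float = 0.01

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ConfigurationError("n_points must be >= 2")
        if self.dt_report <= 0:
            raise ConfigurationError("dt_report must be > 0")

    @property
    def duration(self) -> float:
        return self.n_points * self.dt_report

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt_report * np.arange(self.n_points + 1)

    @classmethod
    def hourly(cls, duration: float = 22.0) -> "SimulationGrid":
        """Coarse grid reporting once per hour (useful during fitting)."""
        return cls(n_points=int(round(duration)), dt_report=1.0)


@dataclass
class Trajectory:
    """Simulated time course: states per report time plus the normalized
    target-transcript readout."""

    times: np.ndarray
    states: np.ndarray  # (n_times, 9), columns in STATE_NAMES order
    target_norm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        raw = self.target_raw
        if np.max(raw) > 0:
            self.target_norm = normalize_to_max100(raw)
        else:
            self.target_norm = np.zeros_like(raw)

    @property
    def target_raw(self) -> np.ndarray:
        return self.states[:, 8]

    def species(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    @property
    def peak_time(self) -> float:
        """Time of the maximum normalized target (first index on ties)."""
        return float(self.times[int(np.argmax(self.target_norm))])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time_h", self.times)
        df["target_norm"] = self.target_norm
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_rhs(
    arch: ModelArchitecture | str,
    params: ParameterSet,
    inhibitor: bool = False,
) -> Callable[[np.ndarray, float], np.ndarray]:
    """Return the derivative function ``f(state, t) -> dstate/dt``.

    The system is autonomous; ``t`` is accepted for solver compatibility
    and ignored.  The inhibitor flag zeroes the catalytic
    ADP-ribosylation rate, emulating treatment with a catalytic PARP7
    inhibitor such as RBN2397.
    """
    arch = ModelArchitecture.coerce(arch)
    p = params.to_vector()
    k_cat = 0.0 if inhibitor else params.k_cat_adp
    code = arch.code

    def f(y: np.ndarray, t: float = 0.0) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        dy = np.empty(_ode.N_STATE)
        _ode.rhs(code, p, y, k_cat, dy)
        return dy

    return f


_STATUS_MESSAGES = {
    _ode.MAX_STEPS_EXCEEDED: "step budget exhausted (stiffness beyond solver limits)",
    _ode.NONFINITE: "non-finite state encountered",
    _ode.NEGATIVE_STATE: "state fell below -1e-8",
}


def simulate(
    arch: ModelArchitecture | str,
    params: ParameterSet,
    init: InitialConditions | None = None,
    grid: SimulationGrid | None = None,
    inhibitor: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    max_steps: int = 200_000,
    state0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate one architecture over the reporting grid.

    Uses an adaptive stiff Rosenbrock(2,3) method with analytic Jacobian.
    States within ``[-1e-8, 0)`` at report points are clamped to zero;
    anything lower, a non-finite state, or an exhausted step budget raises
    :class:`InvalidSimulation`.  ``state0`` overrides the full initial
    state vector (ordered as :data:`STATE_NAMES`), e.g. to start from a
    pre-formed promoter complex.
    """
    arch = ModelArchitecture.coerce(arch)
    init = init or InitialConditions()
    grid = grid or SimulationGrid()
    if state0 is not None:
        y0 = np.asarray(state0, dtype=float).copy()
        if y0.shape != (_ode.N_STATE,):
            raise ConfigurationError(
                f"state0 must have {_ode.N_STATE} entries")
    else:
        y0 = init.state_vector(arch)
    t_out = grid.times
    Y, status = _ode.integrate(
        arch.code, params.to_vector(), y0, t_out, bool(inhibitor),
        rtol, atol, max_steps)
    if status != _ode.OK:
        raise InvalidSimulation(_STATUS_MESSAGES.get(status, "solver failure"))
    if not np.all(np.isfinite(Y)):
        raise InvalidSimulation("non-finite state in report")
    np.clip(Y, 0.0, None, out=Y)
    return Trajectory(times=t_out, states=Y)


def simulate_paired(
    arch: ModelArchitecture | str,
    params: ParameterSet,
    init: InitialConditions | None = None,
    grid: SimulationGrid | None = None,
    **kwargs,
) -> tuple[Trajectory, Trajectory]:
    """Simulate the control and PARP7-inhibitor conditions side by side.

    Both members share parameters, initial conditions, and grid; only the
    ADP-ribosylation rate constant differs (forced to zero under
    inhibitor).
    """
    control = simulate(arch, params, init, grid, inhibitor=False, **kwargs)
    inhib = simulate(arch, params, init, grid, inhibitor=True, **kwargs)
    return control, inhib


def normalize_to_max100(series: Sequence[float]) -> np.ndarray:
    """Scale a series so its maximum equals 100."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise NormalizationError("empty series")
    if not np.all(np.isfinite(arr)):
        raise NormalizationError("series contains non-finite values")
    m = arr.max()
    if m <= 0:
        raise NormalizationError(f"series maximum must be > 0, got {m}")
    return 100.0 * arr / m


def ratio_scan(
    arch: ModelArchitecture | str,
    params: ParameterSet,
    ratios: Sequence[float],
    P0: float = 100.0,
    grid: SimulationGrid | None = None,
    **kwargs,
) -> dict[float, tuple[Trajectory | None, float | None]]:
    """Scan the initial AR:promoter ratio and record the target peak time.

    For each ratio the control condition is simulated with
    ``AR0 = ratio * P0``.  Higher ratios buffer the feedback: excess AR
    refills promoters as modified AR is cleared, delaying the decline in
    transcriptional output.  Failed ratios are recorded as
    ``(None, None)`` and the scan continues.
    """
    results: dict[float, tuple[Trajectory | None, float | None]] = {}
    for r in ratios:
        if r <= 0:
            raise ConfigurationError(f"ratio must be > 0, got {r}")
        init = InitialConditions(AR0=r * P0, P0=P0)
        try:
            traj = simulate(arch, params, init, grid, inhibitor=False, **kwargs)
        except InvalidSimulation:
            results[float(r)] = (None, None)
            continue
        results[float(r)] = (traj, traj.peak_time)
    return results
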