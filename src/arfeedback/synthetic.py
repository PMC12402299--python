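"""Synthetic observed-profile generator.

Emulates the statistical structure of the composite qPCR time course the
models are fitted to: a latent transcript trajectory simulated from a
known ("truth") parameter set, read out as several genes that are noisy
replicates of the latent profile, averaged into a composite, interpolated
to an hourly grid, and normalized per condition to a maximum of 100.
Under control the packaged reference parameters produce a single
transcript peak near 8 h followed by a decline; under PARP7 inhibition
the decline is absent.

Noise is multiplicative Gaussian (coefficient of variation ``noise_cv``)
on the raw transcript, mimicking replicate error that scales with signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fitting import ObservedProfile
from .models import (
    ConfigurationError,
    InitialConditions,
    InvalidSimulation,
    ModelArchitecture,
    ParameterSet,
    SimulationGrid,
    Trajectory,
    normalize_to_max100,
    simulate_paired,
)

__all__ = [
    "REFERENCE_PARAMS",
    "SynthConfig",
    "generate_ground_truth",
    "make_gene_profiles",
    "composite_average",
    "interpolate_profile",
    "make_observed",
]

#: Reference chromatin-model parameter set (rates per hour).  A repository
#: fixture chosen so the control composite peaks near 8 h and declines,
#: the inhibitor condition keeps rising, modified AR binds the promoter
#: more weakly than unmodified AR, and excess AR buffers the feedback
#: delay; not an experimentally fitted set.
REFERENCE_PARAMS = ParameterSet(
    k_trl_ar=0.1,
    k_tx_ar=1.0,
    k_rep_ar=0.001,
    k_deg_arm=0.3,
    k_on_AR=0.2,
    k_off_AR=1.0,
    k_on_ADP=0.005,
    k_off_ADP=20.0,
    k_cat_adp=0.03,
    k_deg_adp=2.0,
    k_tx_p7=0.1,
    k_deg_p7m=0.3,
    k_trl_p7=1.0,
    k_deg_p7_fast=2.0,
    k_deg_p7_slow=0.1,
    K_stab=300.0,
    k_tx_target=1.0,
    k_deg_target=0.5,
)


def _default_sample_times() -> np.ndarray:
    return np.arange(0.0, 23.0, 2.0)


def _default_interp_grid() -> np.ndarray:
    return np.arange(0.0, 23.0, 1.0)


@dataclass(frozen=True)
class SynthConfig:
    """Conditions for synthetic profile generation.

    Defaults: chromatin truth architecture with the packaged reference
    parameters, sampling every 2 h over 0-22 h, three genes, 5%
    multiplicative noise, hourly interpolation grid.
    """

    truth_arch: ModelArchitecture = ModelArchitecture.CHROMATIN
    truth_params: ParameterSet = REFERENCE_PARAMS
    sample_times: np.ndarray = field(default_factory=_default_sample_times)
    n_genes: int = 3
    noise_cv: float = 0.05
    interp_grid: np.ndarray = field(default_factory=_default_interp_grid)
    seed: int = 0
    init: InitialConditions = field(default_factory=InitialConditions)
    grid: SimulationGrid = field(default_factory=SimulationGrid)

    def __post_init__(self) -> None:
        object.__setattr__(self, "truth_arch",
                           ModelArchitecture.coerce(self.truth_arch))
        object.__setattr__(self, "sample_times",
                           np.asarray(self.sample_times, dtype=float))
        object.__setattr__(self, "interp_grid",
                           np.asarray(self.interp_grid, dtype=float))
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        t = self.sample_times
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("sample_times must be strictly increasing")
        span = self.grid.t_start, self.grid.t_start + self.grid.duration
        if t[0] < span[0] or t[-1] > span[1] + 1e-12:
            raise ConfigurationError("sample_times outside simulation grid")


def generate_ground_truth(
    config: SynthConfig,
) -> tuple[Trajectory, Trajectory]:
    """Noise-free paired (control, inhibitor) trajectories from the truth
    parameters; deterministic, no random draws consumed."""
    try:
        return simulate_paired(config.truth_arch, config.truth_params,
                               config.init, config.grid)
    except InvalidSimulation as exc:
        raise ConfigurationError(
            f"truth parameter set failed to simulate: {exc}") from exc


def make_gene_profiles(
    truth: Trajectory,
    config: SynthConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """(n_genes, n_sample_times) matrix of noisy replicates of the latent
    raw target profile; negative draws are clamped to zero."""
    t = config.sample_times
    if t[0] < truth.times[0] or t[-1] > truth.times[-1] + 1e-12:
        raise ConfigurationError("sample_times outside trajectory span")
    latent = np.interp(t, truth.times, truth.target_raw)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eps = rng.normal(0.0, config.noise_cv, size=(config.n_genes, t.size))
    return np.clip(latent[None, :] * (1.0 + eps), 0.0, None)


def composite_average(gene_matrix: np.ndarray) -> np.ndarray:
    """Unweighted mean across genes at each time point."""
    m = np.asarray(gene_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ConfigurationError("gene matrix must be 2-D with >= 1 gene")
    return m.mean(axis=0)


def interpolate_profile(
    times: Sequence[float],
    values: Sequence[float],
    target_times: Sequence[float],
) -> np.ndarray:
    """Piecewise-linear interpolation; extrapolation is an error."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    tt = np.asarray(target_times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError("times must be strictly increasing")
    if tt.min() < t[0] - 1e-12 or tt.max() > t[-1] + 1e-12:
        raise ConfigurationError("target_times outside the sampled span")
    return np.interp(tt, t, v)


def make_observed(
    config: SynthConfig,
) -> tuple[ObservedProfile, ObservedProfile]:
    """Full pipeline: ground truth -> per-gene noise -> composite average
    -> hourly interpolation -> per-condition normalization to max 100.

    Returns ``(observed, latent)`` where the latent profile ran the same
    pipeline without noise (for oracle comparisons).
    """
    control, inhibitor = generate_ground_truth(config)
    rng = np.random.default_rng(config.seed)

    def _condition(truth: Trajectory, noisy: bool) -> np.ndarray:
        if noisy:
            genes = make_gene_profiles(truth, config, rng)
        else:
            latent = np.interp(config.sample_times, truth.times,
                               truth.target_raw)
            genes = np.tile(latent, (config.n_genes, 1))
        comp = composite_average(genes)
        interp = interpolate_profile(config.sample_times, comp,
                                     config.interp_grid)
        return normalize_to_max100(interp)

    observed = ObservedProfile(
        times=config.interp_grid,
        control_values=_condition(control, True),
        inhibitor_values=_condition(inhibitor, True))
    latent = ObservedProfile(
        times=config.interp_grid,
        control_values=_condition(control, False),
        inhibitor_values=_condition(inhibitor, False))
    return observed, latent
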