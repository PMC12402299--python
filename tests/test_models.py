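"""Unit and property tests for the ODE model layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from arfeedback import (
    ConfigurationError,
    InitialConditions,
    InvalidSimulation,
    ModelArchitecture,
    NormalizationError,
    ParameterSet,
    SimulationGrid,
    build_rhs,
    normalize_to_max100,
    ratio_scan,
    simulate,
    simulate_paired,
)
from arfeedback.models import STATE_NAMES

from conftest import random_parameter_set

ARCHS = ["simple", "chromatin", "nucleoplasm"]
IDX = {name: i for i, name in enumerate(STATE_NAMES)}


def _state(**kwargs):
    y = np.zeros(len(STATE_NAMES))
    for name, value in kwargs.items():
        y[IDX[name]] = value
    return y


class TestBuildRhs:
    @pytest.mark.parametrize("arch", ARCHS)
    def test_all_rates_zero_gives_null_dynamics(self, arch):
        f = build_rhs(arch, ParameterSet())
        y = _state(mRNA_AR=3.0, AR_free=660.0, P_free=100.0, C_AR=5.0,
                   mRNA_P7=1.0, P7=2.0, T=7.0)
        assert np.all(f(y) == 0.0)

    @pytest.mark.parametrize("arch", ARCHS)
    def test_inhibitor_flag_equals_zero_catalytic_rate(self, arch,
                                                       reference_params):
        f_inhib = build_rhs(arch, reference_params, inhibitor=True)
        f_zero = build_rhs(arch, reference_params.replace(k_cat_adp=0.0))
        y = _state(mRNA_AR=1.0, AR_free=400.0, AR_adp_free=10.0,
                   P_free=60.0, C_AR=30.0, C_ADP=10.0,
                   mRNA_P7=2.0, P7=15.0, T=40.0)
        np.testing.assert_array_equal(f_inhib(y), f_zero(y))

    def test_single_binding_term_hand_expansion(self):
        # only AR-promoter association active: flux k_on * AR_free * P_free
        f = build_rhs("chromatin", ParameterSet(k_on_AR=0.01))
        y = _state(AR_free=660.0, P_free=100.0)
        dy = f(y)
        flux = 0.01 * 660.0 * 100.0
        assert dy[IDX["C_AR"]] == pytest.approx(flux)
        assert dy[IDX["P_free"]] == pytest.approx(-flux)
        assert dy[IDX["AR_free"]] == pytest.approx(-flux)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ConfigurationError):
            build_rhs("cytoplasm", ParameterSet())


class TestParameterSet:
    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            ParameterSet(k_tx_ar=-1.0)

    def test_fast_slow_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            ParameterSet(k_deg_p7_fast=0.1, k_deg_p7_slow=1.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError):
            ParameterSet.from_dict({"k_tx_ar": 1.0, "k_mystery": 2.0})

    def test_vector_round_trip(self, reference_params):
        again = ParameterSet.from_vector(reference_params.to_vector())
        assert again == reference_params

    def test_binding_parameters_inactive_for_simple(self, reference_params):
        active = reference_params.active_dict("simple")
        for name in ("k_on_AR", "k_off_AR", "k_on_ADP", "k_off_ADP"):
            assert active[name] is None
        assert active["k_cat_adp"] == reference_params.k_cat_adp
        assert ModelArchitecture.SIMPLE.n_params == 14
        assert ModelArchitecture.CHROMATIN.n_params == 18


class TestSimulate:
    def test_null_dynamics_hold_initial_state(self):
        traj = simulate("chromatin", ParameterSet(),
                        grid=SimulationGrid(n_points=50, dt_report=0.1))
        assert np.all(traj.species("AR_free") == 660.0)
        assert np.all(traj.target_raw == 0.0)
        assert np.all(traj.target_norm == 0.0)

    def test_frozen_complex_matches_analytic_exponential(self):
        # with binding frozen and only transcription/decay active, T(t)
        # follows the single-compartment solution
        c0, ktx, kdeg = 40.0, 2.0, 0.5
        params = ParameterSet(k_tx_target=ktx, k_deg_target=kdeg)
        state0 = _state(C_AR=c0, P_free=60.0)
        grid = SimulationGrid(n_points=220, dt_report=0.1)
        traj = simulate("chromatin", params, grid=grid, state0=state0)
        expected = (ktx * c0 / kdeg) * (1.0 - np.exp(-kdeg * traj.times))
        np.testing.assert_allclose(traj.target_raw[1:], expected[1:],
                                   rtol=1e-4)

    def test_inhibitor_never_produces_modified_species(self, reference_params):
        traj = simulate("chromatin", reference_params, inhibitor=True)
        assert np.all(traj.species("AR_adp_free") == 0.0)
        assert np.all(traj.species("C_ADP") == 0.0)

    def test_minimal_two_point_grid(self, reference_params):
        grid = SimulationGrid(n_points=2, dt_report=0.5)
        control, inhib = simulate_paired("chromatin", reference_params,
                                         grid=grid)
        assert control.times.size == 3  # initial state + 2 reports

    def test_trajectory_csv_round_trip(self, tmp_path, reference_params):
        traj = simulate("chromatin", reference_params,
                        grid=SimulationGrid(n_points=20, dt_report=1.0))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert list(df.columns) == ["time_h", *STATE_NAMES, "target_norm"]
        np.testing.assert_allclose(df["T"].to_numpy(), traj.target_raw)

    def test_agrees_with_scipy_lsoda(self, reference_params):
        """Independent solver cross-check at tight tolerance."""
        from scipy.integrate import solve_ivp

        f = build_rhs("chromatin", reference_params)
        grid = SimulationGrid(n_points=44, dt_report=0.5)
        traj = simulate("chromatin", reference_params, grid=grid)
        sol = solve_ivp(lambda t, y: f(y, t), (0.0, 22.0),
                        InitialConditions().state_vector("chromatin"),
                        t_eval=grid.times, method="LSODA",
                        rtol=1e-9, atol=1e-11)
        np.testing.assert_allclose(traj.states, sol.y.T, rtol=2e-4,
                                   atol=1e-6)


class TestSimulatePaired:
    def test_zero_catalytic_rate_gives_identical_pair(self, reference_params):
        params = reference_params.replace(k_cat_adp=0.0)
        control, inhib = simulate_paired("chromatin", params)
        np.testing.assert_array_equal(control.states, inhib.states)

    def test_degradation_reduces_unmodified_ar_vs_inhibitor(
            self, reference_params):
        control, inhib = simulate_paired("chromatin", reference_params)
        total_c = control.species("AR_free")[-1] + control.species("C_AR")[-1]
        total_i = inhib.species("AR_free")[-1] + inhib.species("C_AR")[-1]
        assert total_c <= total_i


class TestNormalize:
    def test_linear_scaling(self):
        np.testing.assert_allclose(normalize_to_max100([5, 10, 2.5]),
                                   [50.0, 100.0, 25.0])

    def test_constant_series(self):
        np.testing.assert_allclose(normalize_to_max100([3.0, 3.0, 3.0]),
                                   [100.0, 100.0, 100.0])

    @pytest.mark.parametrize("bad", [[0.0, 0.0], [-1.0, -2.0], []])
    def test_degenerate_series_rejected(self, bad):
        with pytest.raises(NormalizationError):
            normalize_to_max100(bad)


class TestRatioScan:
    def test_consistent_with_default_simulation(self, reference_params):
        grid = SimulationGrid(n_points=220, dt_report=0.1)
        result = ratio_scan("chromatin", reference_params, [6.6], P0=100,
                            grid=grid)
        traj, peak = result[6.6]
        direct = simulate("chromatin", reference_params,
                          InitialConditions(AR0=660, P0=100), grid)
        np.testing.assert_array_equal(traj.states, direct.states)
        assert peak == direct.peak_time

    def test_no_feedback_peaks_at_final_time(self, reference_params):
        params = reference_params.replace(k_cat_adp=0.0)
        grid = SimulationGrid(n_points=110, dt_report=0.2)
        result = ratio_scan("chromatin", params, [1.65, 6.6], grid=grid)
        for _, peak in result.values():
            assert peak == pytest.approx(grid.duration)

    def test_nonpositive_ratio_rejected(self, reference_params):
        with pytest.raises(ConfigurationError):
            ratio_scan("chromatin", reference_params, [0.0])


# ---------------------------------------------------------------------------
# property-based invariants

_PROPERTY_GRID = SimulationGrid(n_points=110, dt_report=0.2)


@st.composite
def parameter_sets(draw):
    seed = draw(st.integers(min_value=0, max_value=2**31 - 1))
    return random_parameter_set(np.random.default_rng(seed))


@settings(max_examples=30, derandomize=True, deadline=None)
@given(params=parameter_sets(),
       arch=st.sampled_from(["chromatin", "nucleoplasm"]))
def test_promoter_conservation_property(params, arch):
    """P_free + C_AR + C_ADP stays at P0 for random valid parameters."""
    try:
        traj = simulate(arch, params, grid=_PROPERTY_GRID)
    except InvalidSimulation:
        return
    total = (traj.species("P_free") + traj.species("C_AR")
             + traj.species("C_ADP"))
    assert np.max(np.abs(total - 100.0)) < 1e-4


@settings(max_examples=30, derandomize=True, deadline=None)
@given(params=parameter_sets(), arch=st.sampled_from(ARCHS))
def test_reported_states_nonnegative_property(params, arch):
    try:
        traj = simulate(arch, params, grid=_PROPERTY_GRID)
    except InvalidSimulation:
        return
    assert np.min(traj.states) >= 0.0  # clamped from no lower than -1e-8


@settings(max_examples=15, derandomize=True, deadline=None)
@given(params=parameter_sets(), arch=st.sampled_from(ARCHS))
def test_inhibitor_null_equivalence_property(params, arch):
    params = params.replace(k_cat_adp=0.0)
    try:
        control, inhib = simulate_paired(arch, params, grid=_PROPERTY_GRID)
    except InvalidSimulation:
        return
    np.testing.assert_array_equal(control.states, inhib.states)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(params=parameter_sets(),
       arch=st.sampled_from(["chromatin", "nucleoplasm"]))
def test_total_ar_conserved_without_sources_or_sinks(params, arch):
    """With no AR production and no degradation of the modified form, the
    total AR pool (free + modified + complexed) is invariant."""
    params = params.replace(k_deg_adp=0.0, k_tx_ar=0.0, k_trl_ar=0.0)
    try:
        traj = simulate(arch, params, grid=_PROPERTY_GRID)
    except InvalidSimulation:
        return
    total = (traj.species("AR_free") + traj.species("AR_adp_free")
             + traj.species("C_AR") + traj.species("C_ADP"))
    assert np.max(np.abs(total - 660.0)) < 1e-4
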