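"""Forward-model tests: dynamics, fixed point, linearization, spectra."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp
from scipy.signal import welch

from spectralcmc import cmc

from conftest import stable_draws


# ---------------------------------------------------------------------------
# structure and parameter packing
# ---------------------------------------------------------------------------

def test_population_ordering_fixed():
    assert cmc.POPULATIONS == ("ss", "sp", "ii", "dp")


def test_edge_sets():
    assert cmc.EXCITATORY_EDGES == (("ss", "sp"), ("ss", "ii"), ("dp", "ii"))
    assert cmc.INHIBITORY_EDGES == (("sp", "ss"), ("ii", "ss"), ("ii", "dp"))


def test_parameter_partition():
    assert cmc.N_NEURONAL == 14
    exc = [n for n in cmc.NEURONAL_PARAM_NAMES if n.startswith("g_")
           and tuple(n[2:].split("_")) in cmc.EXCITATORY_EDGES]
    inh = [n for n in cmc.NEURONAL_PARAM_NAMES if n.startswith("g_")
           and tuple(n[2:].split("_")) in cmc.INHIBITORY_EDGES]
    self_mod = [n for n in cmc.NEURONAL_PARAM_NAMES if n.startswith("s_")]
    taus = [n for n in cmc.NEURONAL_PARAM_NAMES if n.startswith("tau_")]
    assert (len(exc), len(inh), len(self_mod), len(taus)) == (3, 3, 4, 4)


def test_pack_unpack_roundtrip():
    rng = np.random.default_rng(0)
    vec = rng.normal(0, 0.2, cmc.N_PARAMS)
    vec[cmc.PARAM_NAMES.index("innov_exponent")] = 1.3
    p, o = cmc.unpack_parameters(vec)
    np.testing.assert_allclose(cmc.pack_parameters(p, o), vec, atol=1e-12)


def test_innovation_exponent_clipped():
    vec = np.zeros(cmc.N_PARAMS)
    vec[cmc.PARAM_NAMES.index("innov_exponent")] = 5.0
    _, o = cmc.unpack_parameters(vec)
    assert o.innov_exponent == 2.0


# ---------------------------------------------------------------------------
# sigmoid
# ---------------------------------------------------------------------------

def test_sigmoid_zero():
    assert cmc.sigmoid_response(0.0) == 0.0


def test_sigmoid_saturation():
    assert cmc.sigmoid_response(1e3) == pytest.approx(0.5, abs=1e-12)
    assert cmc.sigmoid_response(-1e3) == pytest.approx(-0.5, abs=1e-12)


def test_sigmoid_closed_form():
    expected = 1.0 / (1.0 + np.exp(-2.0 / 3.0)) - 0.5
    assert cmc.sigmoid_response(1.0) == pytest.approx(expected, rel=1e-12)


@given(st.floats(-50, 50), st.floats(-50, 50))
def test_sigmoid_monotone(a, b):
    lo, hi = sorted((a, b))
    assert cmc.sigmoid_response(lo) <= cmc.sigmoid_response(hi)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def test_zero_state_is_equilibrium(base_params):
    d = cmc.state_derivatives(np.zeros(8), base_params)
    np.testing.assert_allclose(d, 0.0, atol=1e-15)


def test_nonfinite_state_rejected(base_params):
    state = np.zeros(8)
    state[3] = np.nan
    with pytest.raises(FloatingPointError):
        cmc.state_derivatives(state, base_params)


def _decoupled_impulse_peak(tau_scale):
    """Peak time of a single population's impulse response, all couplings
    silenced; the membrane kernel is an alpha function peaking at t=τ."""
    params = cmc.CMCParameters(
        excitatory_coupling=(-30.0, -30.0, -30.0),
        inhibitory_coupling=(-30.0, -30.0, -30.0),
        self_modulation=(-30.0,) * 4,
        time_constants=(tau_scale, 0.0, 0.0, 0.0))
    tau = cmc.BASE_TAU_MS[0] * 1e-3 * np.exp(tau_scale)  # seconds

    def rhs(t, x):
        return cmc.state_derivatives(x, params)

    x0 = np.zeros(8)
    x0[4] = 1.0  # current impulse in the ss population
    sol = solve_ivp(rhs, (0.0, 10.0 * tau), x0, max_step=tau / 200)
    return sol.t[np.argmax(sol.y[0])], tau


def test_impulse_response_peaks_at_tau():
    t_peak, tau = _decoupled_impulse_peak(0.0)
    assert t_peak == pytest.approx(tau, rel=0.02)


def test_doubling_tau_doubles_peak_time():
    t1, _ = _decoupled_impulse_peak(0.0)
    t2, _ = _decoupled_impulse_peak(np.log(2.0))
    assert t2 / t1 == pytest.approx(2.0, rel=0.03)


# ---------------------------------------------------------------------------
# fixed point
# ---------------------------------------------------------------------------

def test_fixed_point_origin_for_zero_input(base_params):
    x = cmc.find_fixed_point(base_params)
    np.testing.assert_allclose(x, 0.0, atol=1e-12)


def test_fixed_point_matches_long_integration(base_params):
    drive = np.array([0.05, 0.0, 0.02, 0.0])
    x_star = cmc.find_fixed_point(base_params, tonic_input=drive)
    assert np.max(np.abs(
        cmc.state_derivatives(x_star, base_params, exogenous_input=drive)
    )) < 1e-9
    sol = solve_ivp(lambda t, x: cmc.state_derivatives(
        x, base_params, exogenous_input=drive),
        (0.0, 10.0), np.zeros(8), rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(sol.y[:, -1], x_star, atol=1e-6)


def test_fixed_point_residuals_for_prior_draws():
    for params, _ in stable_draws(10, seed=42):
        x = cmc.find_fixed_point(params)
        assert np.max(np.abs(cmc.state_derivatives(x, params))) < 1e-9


def test_fixed_point_nonconvergence_error():
    params = cmc.CMCParameters(excitatory_coupling=(12.0, 12.0, 12.0))
    with pytest.raises(cmc.FixedPointError, match="residual"):
        cmc.find_fixed_point(params,
                             tonic_input=np.array([5.0, 5.0, 5.0, 5.0]),
                             max_iterations=5)


# ---------------------------------------------------------------------------
# linearization
# ---------------------------------------------------------------------------

def test_jacobian_current_damping_diagonal(base_params):
    J = cmc.linearize(base_params)
    taus = cmc.BASE_TAU_MS * 1e-3 * np.exp(base_params.time_constants)
    np.testing.assert_allclose(np.diag(J)[4:], -2.0 / taus, rtol=1e-12)
    # potential rows: v̇ = i
    np.testing.assert_allclose(J[:4, 4:], np.eye(4), atol=1e-15)
    np.testing.assert_allclose(J[:4, :4], 0.0, atol=1e-15)


def test_jacobian_matches_finite_differences():
    for params, _ in stable_draws(3, seed=1):
        J = cmc.linearize(params)
        x0 = np.zeros(8)
        eps = 1e-6
        J_fd = np.empty((8, 8))
        for j in range(8):
            dx = np.zeros(8)
            dx[j] = eps
            J_fd[:, j] = (cmc.state_derivatives(x0 + dx, params)
                          - cmc.state_derivatives(x0 - dx, params)) / (2 * eps)
        np.testing.assert_allclose(J, J_fd, rtol=1e-6, atol=1e-9)


def test_prior_mean_jacobian_stable(base_params):
    assert np.linalg.eigvals(cmc.linearize(base_params)).real.max() < 0


# ---------------------------------------------------------------------------
# transfer function and PSD
# ---------------------------------------------------------------------------

def test_transfer_function_lorentzian():
    a = 3.0
    J = np.array([[-a]])
    grid = cmc.default_grid()
    T = cmc.transfer_function(J, np.array([1.0]), np.array([1.0]), grid)
    expected = 1.0 / (a**2 + (2 * np.pi * grid) ** 2)
    np.testing.assert_allclose(np.abs(T) ** 2, expected, rtol=1e-10)


def test_transfer_function_rolloff(base_params):
    J = cmc.linearize(base_params)
    b = np.zeros(8); b[4] = 1.0
    c = np.zeros(8); c[1] = 1.0
    lo = cmc.transfer_function(J, b, c, np.array([1.0]))
    hi = cmc.transfer_function(J, b, c, np.array([1e6]))
    assert np.abs(hi[0]) < 1e-6 * np.abs(lo[0])


def test_transfer_function_rejects_unstable():
    with pytest.raises(cmc.InstabilityError):
        cmc.transfer_function(np.array([[0.1]]), np.array([1.0]),
                              np.array([1.0]), np.array([1.0]))


def test_psd_shape_and_positivity(base_psd, grid):
    assert base_psd.shape == (60,)
    assert np.all(base_psd > 0)
    assert grid[0] == 1.0 and grid[-1] == 60.0


def test_zero_innovation_gives_noise_floor(base_params, grid):
    obs = cmc.ObservationParameters(log_innov_amp=-np.inf)
    psd = cmc.predict_psd(base_params, obs, grid)
    floor = (np.exp(obs.log_noise_white)
             + np.exp(obs.log_noise_pink) / grid)
    np.testing.assert_allclose(psd, floor, rtol=1e-12)


def test_log_gain_scales_neuronal_spectrum(base_params, base_obs, grid):
    quiet = cmc.ObservationParameters(log_noise_white=-np.inf,
                                      log_noise_pink=-np.inf)
    psd0 = cmc.predict_psd(base_params, quiet, grid)
    bumped = cmc.ObservationParameters(log_gain=quiet.log_gain + 0.7,
                                       log_noise_white=-np.inf,
                                       log_noise_pink=-np.inf)
    psd1 = cmc.predict_psd(base_params, bumped, grid)
    np.testing.assert_allclose(psd1, np.exp(0.7) * psd0, rtol=1e-12)


def test_linearized_simulation_matches_psd(base_params, base_obs, grid):
    """Independent time-domain oracle: modal discretization + Welch."""
    signal, fs = cmc.simulate_linearized(base_params, base_obs,
                                         duration=400.0, fs=512.0, seed=9)
    f, pxx = welch(signal, fs=fs, nperseg=int(4 * fs))
    quiet = cmc.ObservationParameters(
        log_gain=base_obs.log_gain, log_innov_amp=base_obs.log_innov_amp,
        innov_exponent=base_obs.innov_exponent,
        log_noise_white=-np.inf, log_noise_pink=-np.inf)
    predicted = cmc.predict_psd(base_params, quiet, grid)
    est = np.interp(grid, f, pxx)
    r = np.corrcoef(np.log(est), np.log(predicted))[0, 1]
    assert r > 0.99
    ratio = est / predicted
    assert np.all(ratio > 0.7) and np.all(ratio < 1.4)


def test_nonlinear_simulation_small_noise(base_params, grid):
    """Heun integration of the full nonlinear system in the small-noise
    regime, compared per frequency after 3-bin smoothing."""
    obs = cmc.ObservationParameters(log_innov_amp=-12.0)
    signal, fs = cmc.simulate_nonlinear(base_params, obs, duration=180.0,
                                        fs=2048.0, seed=17)
    f, pxx = welch(signal, fs=fs, nperseg=int(fs))
    quiet = cmc.ObservationParameters(
        log_gain=obs.log_gain, log_innov_amp=obs.log_innov_amp,
        innov_exponent=obs.innov_exponent,
        log_noise_white=-np.inf, log_noise_pink=-np.inf)
    predicted = cmc.predict_psd(base_params, quiet, grid)
    est = np.interp(grid, f, pxx)
    kernel = np.ones(3) / 3.0
    est_s = np.convolve(est, kernel, mode="same")
    pred_s = np.convolve(predicted, kernel, mode="same")
    r = np.corrcoef(np.log(est_s[1:-1]), np.log(pred_s[1:-1]))[0, 1]
    assert r > 0.99
    ratio = est_s[1:-1] / pred_s[1:-1]
    assert np.all(ratio > 0.7) and np.all(ratio < 1.4)


def test_grid_validation():
    with pytest.raises(ValueError):
        cmc.validate_grid(np.array([0.0, 1.0]))
    with pytest.raises(ValueError):
        cmc.validate_grid(np.array([2.0, 1.0]))
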