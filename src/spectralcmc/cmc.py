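"""Canonical microcircuit (CMC) neural mass model and its spectral forward map.

The CMC couples four neuronal populations — spiny stellate (ss), superficial
pyramidal (sp), inhibitory interneuron (ii) and deep pyramidal (dp) — through
a fixed laminar wiring: three excitatory projections (ss→sp, ss→ii, dp→ii),
three inhibitory projections (sp→ss, ii→ss, ii→dp) and one recurrent
self-inhibition per population.  Each population n obeys a second-order
synaptic convolution,

    dv_n/dt = i_n
    di_n/dt = (H_n/τ_n) Σ_m d_mn σ(v_m) − (2/τ_n) i_n − (1/τ_n²) v_n ,

where σ is a centred sigmoid, H_n a fixed synaptic gain, τ_n a membrane/
synaptic time constant and d_mn the signed connection weights.  The 14 free
neuronal parameters are log-scalings of the coupling weights (3 excitatory,
3 inhibitory, 4 self) and of the time constants (4), applied multiplicatively
to fixed baselines.

Steady-state power spectra follow from linearising the model around its fixed
point: the predicted channel PSD is the squared transfer-function gain from a
power-law neuronal innovation entering the granular (ss) population to the
superficial-pyramidal potential, plus white and 1/f channel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "POPULATIONS",
    "EXCITATORY_EDGES",
    "INHIBITORY_EDGES",
    "NEURONAL_PARAM_NAMES",
    "OBSERVATION_PARAM_NAMES",
    "PARAM_NAMES",
    "N_NEURONAL",
    "N_OBSERVATION",
    "N_PARAMS",
    "CMCParameters",
    "ObservationParameters",
    "InstabilityError",
    "FixedPointError",
    "default_grid",
    "validate_grid",
    "sigmoid_response",
    "state_derivatives",
    "find_fixed_point",
    "linearize",
    "transfer_function",
    "innovation_spectrum",
    "predict_psd",
    "pack_parameters",
    "unpack_parameters",
    "simulate_linearized",
    "simulate_nonlinear",
]

# Population order is fixed everywhere: (ss, sp, ii, dp).
POPULATIONS = ("ss", "sp", "ii", "dp")

EXCITATORY_EDGES = (("ss", "sp"), ("ss", "ii"), ("dp", "ii"))
INHIBITORY_EDGES = (("sp", "ss"), ("ii", "ss"), ("ii", "dp"))

# Fixed constants (not free parameters).
SIGMOID_SLOPE = 2.0 / 3.0
#: synaptic gain per receiving population, mV; inputs onto the inhibitory
#: interneurons carry the large "inhibitory-class" gain
FIXED_GAINS_MV = np.array([4.0, 4.0, 32.0, 4.0])
#: baseline time constants, ms — fast granular/superficial, slow ii/dp
BASE_TAU_MS = np.array([2.0, 2.0, 16.0, 28.0])
#: baseline magnitude of every inter-population coupling weight; chosen so
#: the prior-mean circuit is stable with an alpha-range (~11 Hz) resonance
BASE_COUPLING = 40.0
#: baseline magnitude of recurrent self-inhibition
BASE_SELF = 4.0
#: fixed amplitude scale of the neuronal innovation entering the granular
#: population; sets the overall power scale so that prior-mean neuronal
#: spectra are of order one (power units are arbitrary)
INPUT_SCALE = 2500.0

NEURONAL_PARAM_NAMES = (
    "g_ss_sp", "g_ss_ii", "g_dp_ii",          # excitatory couplings
    "g_sp_ss", "g_ii_ss", "g_ii_dp",          # inhibitory couplings
    "s_ss", "s_sp", "s_ii", "s_dp",           # self-modulation
    "tau_ss", "tau_sp", "tau_ii", "tau_dp",   # time constants
)
OBSERVATION_PARAM_NAMES = (
    "log_gain", "log_innov_amp", "innov_exponent",
    "log_noise_white", "log_noise_pink",
)
PARAM_NAMES = NEURONAL_PARAM_NAMES + OBSERVATION_PARAM_NAMES
N_NEURONAL = len(NEURONAL_PARAM_NAMES)
N_OBSERVATION = len(OBSERVATION_PARAM_NAMES)
N_PARAMS = N_NEURONAL + N_OBSERVATION

_POP_INDEX = {p: i for i, p in enumerate(POPULATIONS)}


class InstabilityError(RuntimeError):
    """Raised when the linearized model has no stable steady state."""


class FixedPointError(RuntimeError):
    """Raised when the fixed-point search fails to converge."""


def default_grid() -> np.ndarray:
    """The default frequency grid: 1–60 Hz in 1 Hz steps."""
    return np.arange(1.0, 61.0)


def validate_grid(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("frequency grid must be a non-empty 1-D array")
    if np.any(grid <= 0):
        raise ValueError("frequencies must be strictly positive")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("frequencies must be strictly increasing")
    return grid


@dataclass(frozen=True)
class CMCParameters:
    """The 14 free neuronal parameters, as log-scalings of fixed baselines.

    All entries default to zero, i.e. the prior-mean microcircuit.
    """

    excitatory_coupling: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    inhibitory_coupling: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    self_modulation: np.ndarray = field(default_factory=lambda: np.zeros(4))
    time_constants: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self):
        for name, size in (("excitatory_coupling", 3),
                           ("inhibitory_coupling", 3),
                           ("self_modulation", 4), ("time_constants", 4)):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (size,):
                raise ValueError(f"{name} must have shape ({size},)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, arr)

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.excitatory_coupling,
                               self.inhibitory_coupling,
                               self.self_modulation, self.time_constants])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "CMCParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_NEURONAL,):
            raise ValueError(f"expected {N_NEURONAL} neuronal parameters")
        return cls(vec[0:3], vec[3:6], vec[6:10], vec[10:14])

    def effective_tau(self) -> np.ndarray:
        """Effective time constants in seconds."""
        return BASE_TAU_MS * 1e-3 * np.exp(self.time_constants)

    def connectivity(self) -> np.ndarray:
        """Signed 4×4 weight matrix W with W[n, m] the weight of edge m→n."""
        W = np.zeros((4, 4))
        for k, (src, dst) in enumerate(EXCITATORY_EDGES):
            W[_POP_INDEX[dst], _POP_INDEX[src]] = (
                BASE_COUPLING * np.exp(self.excitatory_coupling[k]))
        for k, (src, dst) in enumerate(INHIBITORY_EDGES):
            W[_POP_INDEX[dst], _POP_INDEX[src]] = (
                -BASE_COUPLING * np.exp(self.inhibitory_coupling[k]))
        for n in range(4):
            W[n, n] = -BASE_SELF * np.exp(self.self_modulation[n])
        return W


@dataclass(frozen=True)
class ObservationParameters:
    """Electrode gain, neuronal innovation spectrum and channel noise.

    The innovation spectrum is S_u(f) = exp(log_innov_amp) / f**innov_exponent
    and channel noise adds exp(log_noise_white) + exp(log_noise_pink)/f to the
    predicted power.
    """

    log_gain: float = 0.0
    log_innov_amp: float = 0.0
    innov_exponent: float = 1.0
    log_noise_white: float = -6.0
    log_noise_pink: float = -6.0

    def __post_init__(self):
        if not 0.0 <= self.innov_exponent <= 2.0:
            raise ValueError("innov_exponent must lie in [0, 2]")

    def to_vector(self) -> np.ndarray:
        return np.array([self.log_gain, self.log_innov_amp,
                         self.innov_exponent, self.log_noise_white,
                         self.log_noise_pink])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ObservationParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_OBSERVATION,):
            raise ValueError(f"expected {N_OBSERVATION} observation parameters")
        # the power-law exponent is box-constrained; clip so that arbitrary
        # optimizer iterates remain valid
        return cls(vec[0], vec[1], float(np.clip(vec[2], 0.0, 2.0)),
                   vec[3], vec[4])


def pack_parameters(params: CMCParameters,
                    obs: ObservationParameters) -> np.ndarray:
    """Concatenate neuronal and observation parameters into one vector."""
    return np.concatenate([params.to_vector(), obs.to_vector()])


def unpack_parameters(vec: np.ndarray):
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_PARAMS,):
        raise ValueError(f"expected {N_PARAMS} parameters, got {vec.shape}")
    return (CMCParameters.from_vector(vec[:N_NEURONAL]),
            ObservationParameters.from_vector(vec[N_NEURONAL:]))


def sigmoid_response(v, slope: float = SIGMOID_SLOPE):
    """Centred sigmoid σ(v) = 1/(1+exp(−r v)) − 1/2, bounded in (−1/2, 1/2)."""
    return 1.0 / (1.0 + np.exp(-slope * np.asarray(v, dtype=float))) - 0.5


def _sigmoid_derivative(v, slope: float = SIGMOID_SLOPE):
    s = 1.0 / (1.0 + np.exp(-slope * np.asarray(v, dtype=float)))
    return slope * s * (1.0 - s)


def state_derivatives(state: np.ndarray, params: CMCParameters,
                      exogenous_input: np.ndarray | float = 0.0) -> np.ndarray:
    """Time derivatives of the 8-dimensional state (v_1..4, i_1..4).

    ``exogenous_input`` is a per-population drive added to the summed
    presynaptic input (before the H/τ gain).
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (8,):
        raise ValueError("state must have shape (8,)")
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state (numerical blow-up)")
    v, i = state[:4], state[4:]
    tau = params.effective_tau()
    W = params.connectivity()
    drive = W @ sigmoid_response(v) + np.broadcast_to(
        np.asarray(exogenous_input, dtype=float), (4,))
    di = (FIXED_GAINS_MV / tau) * drive - (2.0 / tau) * i - v / tau**2
    return np.concatenate([i, di])


def linearize(params: CMCParameters,
              state: np.ndarray | None = None) -> np.ndarray:
    """Jacobian of ``state_derivatives`` at ``state`` (default: the origin)."""
    if state is None:
        state = np.zeros(8)
    state = np.asarray(state, dtype=float)
    v = state[:4]
    tau = params.effective_tau()
    W = params.connectivity()
    J = np.zeros((8, 8))
    J[:4, 4:] = np.eye(4)
    J[4:, :4] = (FIXED_GAINS_MV / tau)[:, None] * W * _sigmoid_derivative(v)
    J[4:, :4] -= np.diag(1.0 / tau**2)
    J[4:, 4:] = np.diag(-2.0 / tau)
    return J


def find_fixed_point(params: CMCParameters,
                     tonic_input: np.ndarray | float = 0.0,
                     tolerance: float = 1e-9,
                     max_iterations: int = 100) -> np.ndarray:
    """Newton search for a state x* with ‖f(x*)‖∞ < tolerance.

    With zero tonic input the origin is an exact equilibrium (the sigmoid is
    centred), so the search returns immediately.
    """
    x = np.zeros(8)
    for _ in range(max_iterations):
        f = state_derivatives(x, params, tonic_input)
        residual = np.max(np.abs(f))
        if residual < tolerance:
            return x
        J = linearize(params, x)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise FixedPointError(
                f"singular Jacobian during fixed-point search: {exc}") from exc
        if not np.all(np.isfinite(step)) or np.max(np.abs(step)) > 1e6:
            raise FixedPointError(
                f"fixed-point Newton step diverged (residual {residual:.3e})")
        x = x + step
    residual = np.max(np.abs(state_derivatives(x, params, tonic_input)))
    if residual < tolerance:
        return x
    raise FixedPointError(
        f"fixed point not found in {max_iterations} iterations "
        f"(residual {residual:.3e})")


# Innovations enter the granular (spiny stellate) population; the recorded
# potential is the superficial pyramidal membrane potential.
def _input_vector(params: CMCParameters) -> np.ndarray:
    tau = params.effective_tau()
    b = np.zeros(8)
    b[4] = INPUT_SCALE * FIXED_GAINS_MV[0] / tau[0]  # di_ss/dt
    return b


_OUTPUT_VECTOR = np.zeros(8)
_OUTPUT_VECTOR[1] = 1.0  # v_sp


def transfer_function(jacobian: np.ndarray, input_weights: np.ndarray,
                      output_weights: np.ndarray,
                      grid: np.ndarray) -> np.ndarray:
    """Complex gain T(f) = c·(i2πf·I − J)⁻¹·b on the given frequency grid.

    Computed through the eigendecomposition of the Jacobian so that all
    frequencies share one factorization.  Raises :class:`InstabilityError`
    if any eigenvalue has non-negative real part.
    """
    grid = validate_grid(grid)
    eigvals, eigvecs = np.linalg.eig(jacobian)
    max_real = float(np.max(eigvals.real))
    if max_real >= 0:
        raise InstabilityError(
            f"unstable Jacobian (max real eigenvalue {max_real:.3e}); "
            "steady-state spectrum undefined")
    # T(f) = c V diag(1/(iω − λ)) V⁻¹ b
    beta = np.linalg.solve(eigvecs, input_weights.astype(complex))
    gamma = output_weights.astype(complex) @ eigvecs
    omega = 2j * np.pi * grid
    return (gamma * beta) @ (1.0 / (omega[None, :] - eigvals[:, None]))


def innovation_spectrum(obs: ObservationParameters,
                        grid: np.ndarray) -> np.ndarray:
    """Power-law neuronal innovation spectrum S_u(f) = a / f**α."""
    grid = validate_grid(grid)
    return np.exp(obs.log_innov_amp) / grid**obs.innov_exponent


def predict_psd(params: CMCParameters, obs: ObservationParameters,
                grid: np.ndarray | None = None,
                tonic_input: np.ndarray | float = 0.0) -> np.ndarray:
    """Predicted channel power spectral density on the grid.

    power(f) = exp(log_gain)·|T(f)|²·S_u(f)
             + exp(log_noise_white) + exp(log_noise_pink)/f
    """
    grid = default_grid() if grid is None else validate_grid(grid)
    x_star = find_fixed_point(params, tonic_input)
    J = linearize(params, x_star)
    T = transfer_function(J, _input_vector(params), _OUTPUT_VECTOR, grid)
    neuronal = np.exp(obs.log_gain) * np.abs(T)**2 * innovation_spectrum(
        obs, grid)
    return (neuronal + np.exp(obs.log_noise_white)
            + np.exp(obs.log_noise_pink) / grid)


# ---------------------------------------------------------------------------
# Time-domain simulation oracles
# ---------------------------------------------------------------------------

def _shaped_noise(obs: ObservationParameters, n: int, fs: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian innovation series whose one-sided PSD approximates S_u(f)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    pos = freqs > 0
    amp[pos] = np.sqrt(
        np.exp(obs.log_innov_amp) / freqs[pos]**obs.innov_exponent)
    z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    spectrum = amp * z * np.sqrt(n * fs / 4.0)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = spectrum[-1].real * np.sqrt(2.0)
    return np.fft.irfft(spectrum, n=n)


def simulate_linearized(params: CMCParameters, obs: ObservationParameters,
                        duration: float = 600.0, fs: float = 512.0,
                        seed: int = 0) -> tuple[np.ndarray, float]:
    """Simulate the linearized model driven by shaped noise.

    Returns ``(signal, fs)`` where signal is the measured output (already
    scaled by the electrode gain), without additive channel noise.  Uses
    modal (eigenvector) decoupling and exact zero-order-hold discretization,
    a numerical path independent of the frequency-domain prediction.
    """
    from scipy.signal import lfilter

    rng = np.random.default_rng(seed)
    x_star = find_fixed_point(params)
    J = linearize(params, x_star)
    eigvals, eigvecs = np.linalg.eig(J)
    if np.max(eigvals.real) >= 0:
        raise InstabilityError("unstable Jacobian; cannot simulate steady state")
    b = np.linalg.solve(eigvecs, _input_vector(params).astype(complex))
    c = _OUTPUT_VECTOR.astype(complex) @ eigvecs
    n = int(round(duration * fs))
    u = _shaped_noise(obs, n, fs, rng)
    dt = 1.0 / fs
    y = np.zeros(n, dtype=complex)
    for k in range(eigvals.size):
        lam = eigvals[k]
        a_d = np.exp(lam * dt)
        b_d = b[k] * (a_d - 1.0) / lam  # ZOH: ∫0^dt e^{λs} ds · b
        zk = lfilter([b_d], [1.0, -a_d], u)
        y += c[k] * zk
    return np.exp(0.5 * obs.log_gain) * y.real, fs


def simulate_nonlinear(params: CMCParameters, obs: ObservationParameters,
                       duration: float = 240.0, fs: float = 4096.0,
                       seed: int = 0,
                       decimate_to: float = 512.0) -> tuple[np.ndarray, float]:
    """Heun integration of the full nonlinear model driven by shaped noise.

    Returns the gain-scaled superficial-pyramidal potential, decimated to
    ``decimate_to`` Hz for spectral estimation.  Used as an independent
    oracle for the linearized spectral prediction in the small-noise regime.
    """
    from scipy.signal import decimate

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    u = _shaped_noise(obs, n, fs, rng)
    dt = 1.0 / fs
    tau = params.effective_tau()
    W = params.connectivity()
    gain_over_tau = FIXED_GAINS_MV / tau
    two_over_tau = 2.0 / tau
    inv_tau2 = 1.0 / tau**2
    b_in = np.zeros(4)
    b_in[0] = INPUT_SCALE

    v = np.zeros(4)
    i = np.zeros(4)
    out = np.empty(n)
    slope = SIGMOID_SLOPE
    for k in range(n):
        uk = u[k]
        sig = 1.0 / (1.0 + np.exp(-slope * v)) - 0.5
        dv1 = i
        di1 = gain_over_tau * (W @ sig + b_in * uk) - two_over_tau * i \
            - inv_tau2 * v
        v_e = v + dt * dv1
        i_e = i + dt * di1
        sig_e = 1.0 / (1.0 + np.exp(-slope * v_e)) - 0.5
        dv2 = i_e
        di2 = gain_over_tau * (W @ sig_e + b_in * uk) - two_over_tau * i_e \
            - inv_tau2 * v_e
        v = v + 0.5 * dt * (dv1 + dv2)
        i = i + 0.5 * dt * (di1 + di2)
        out[k] = v[1]
    factor = int(round(fs / decimate_to))
    if factor > 1:
        out = decimate(out, factor, ftype="fir")
        fs = fs / factor
    return np.exp(0.5 * obs.log_gain) * out, fs
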