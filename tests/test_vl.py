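"""Variational Laplace tests: likelihood, free energy, oracle equivalence,
parameter recovery, model comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from spectralcmc import cmc, vl

from conftest import stable_draws


# ---------------------------------------------------------------------------
# log likelihood
# ---------------------------------------------------------------------------

def test_log_likelihood_zero_residuals():
    obs = np.ones(5)
    val = vl.log_likelihood(obs, obs, log_precision=0.3)
    expected = -0.5 * 5 * np.log(2 * np.pi) + 0.5 * 5 * 0.3
    assert val == pytest.approx(expected, rel=1e-12)


def test_log_likelihood_hand_computed():
    observed = np.exp(np.array([0.1, -0.1, 0.0]))
    predicted = np.ones(3)
    val = vl.log_likelihood(observed, predicted, log_precision=0.0)
    expected = -1.5 * np.log(2 * np.pi) - 0.5 * (0.1**2 + 0.1**2)
    assert val == pytest.approx(expected, rel=1e-12)


def test_log_likelihood_quadratic_in_residuals():
    predicted = np.ones(4)
    r = np.array([0.05, -0.02, 0.01, 0.03])
    base = vl.log_likelihood(np.exp(r), predicted, 0.0)
    doubled = vl.log_likelihood(np.exp(2 * r), predicted, 0.0)
    const = -2.0 * np.log(2 * np.pi)
    assert (doubled - const) == pytest.approx(4.0 * (base - const), rel=1e-10)


def test_log_likelihood_rejects_nonpositive():
    with pytest.raises(ValueError):
        vl.log_likelihood(np.array([1.0, -0.5]), np.ones(2), 0.0)


# ---------------------------------------------------------------------------
# free energy components
# ---------------------------------------------------------------------------

def test_complexity_zero_for_identical_gaussians():
    mean = np.zeros(3)
    cov = np.diag([1.0, 2.0, 0.5])
    assert vl.gaussian_kl(mean, cov, mean, cov) == pytest.approx(0.0,
                                                                 abs=1e-12)


def test_kl_nonnegative_random():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a = rng.normal(size=3)
        b = rng.normal(size=3)
        ca = np.diag(rng.uniform(0.1, 2.0, 3))
        cb = np.diag(rng.uniform(0.1, 2.0, 3))
        assert vl.gaussian_kl(a, ca, b, cb) >= -1e-12


@given(st.floats(0.0, 5.0), st.floats(0.0, 5.0))
def test_complexity_monotone_in_mean_shift(d1, d2):
    lo, hi = sorted((d1, d2))
    prior_mean = np.zeros(2)
    cov = np.eye(2) * 0.5
    kl_lo = vl.gaussian_kl(prior_mean + lo, cov, prior_mean, cov)
    kl_hi = vl.gaussian_kl(prior_mean + hi, cov, prior_mean, cov)
    assert kl_hi >= kl_lo - 1e-12


def test_fit_result_decomposition(small_cohort_fits):
    for fr in small_cohort_fits[:5]:
        assert fr.free_energy == pytest.approx(fr.accuracy - fr.complexity,
                                               abs=1e-8)
        assert fr.complexity >= 0


# ---------------------------------------------------------------------------
# linear-Gaussian oracle
# ---------------------------------------------------------------------------

def _linear_gaussian_problem():
    rng = np.random.default_rng(12)
    n, p = 12, 3
    A = rng.normal(size=(n, p))
    theta_true = rng.normal(size=p)
    sigma2 = 0.05
    y = A @ theta_true + rng.normal(0, np.sqrt(sigma2), n)
    prior_mean = np.zeros(p)
    prior_cov = np.eye(p) * 0.8
    return A, y, sigma2, prior_mean, prior_cov


def _conjugate_solution(A, y, sigma2, prior_mean, prior_cov):
    n = y.size
    prec = np.linalg.inv(prior_cov) + A.T @ A / sigma2
    cov = np.linalg.inv(prec)
    mean = cov @ (np.linalg.inv(prior_cov) @ prior_mean + A.T @ y / sigma2)
    marg_cov = A @ prior_cov @ A.T + sigma2 * np.eye(n)
    sign, logdet = np.linalg.slogdet(marg_cov)
    resid = y - A @ prior_mean
    log_ev = -0.5 * (n * np.log(2 * np.pi) + logdet
                     + resid @ np.linalg.solve(marg_cov, resid))
    return mean, cov, log_ev


def test_linear_gaussian_oracle():
    A, y, sigma2, prior_mean, prior_cov = _linear_gaussian_problem()
    mean_x, cov_x, log_ev = _conjugate_solution(A, y, sigma2, prior_mean,
                                                prior_cov)
    prior = vl.PriorSpec(mean=prior_mean, covariance=prior_cov)
    config = vl.FitConfig(max_iterations=200, convergence_tolerance=1e-10,
                          convergence_streak=2,
                          fixed_log_precision=-np.log(sigma2))
    result = vl.fit_model(y, lambda th: A @ th, prior, config=config)
    np.testing.assert_allclose(result.posterior.mean, mean_x, atol=1e-6)
    np.testing.assert_allclose(result.posterior.covariance, cov_x, atol=1e-6)
    assert result.free_energy == pytest.approx(log_ev, abs=1e-6)


def test_free_energy_bound_2d_restriction():
    """F never exceeds the log evidence computed by dense quadrature over a
    2-parameter linear model."""
    rng = np.random.default_rng(5)
    A = rng.normal(size=(8, 2))
    y = A @ np.array([0.4, -0.3]) + rng.normal(0, 0.2, 8)
    sigma2 = 0.04
    prior = vl.PriorSpec(mean=np.zeros(2), covariance=np.eye(2) * 0.5)
    config = vl.FitConfig(max_iterations=100, convergence_tolerance=1e-8,
                          fixed_log_precision=-np.log(sigma2))
    result = vl.fit_model(y, lambda th: A @ th, prior, config=config)
    t = np.linspace(-4, 4, 401)
    T1, T2 = np.meshgrid(t, t, indexing="ij")
    log_joint = np.empty_like(T1)
    for i in range(t.size):
        for j in range(t.size):
            th = np.array([T1[i, j], T2[i, j]])
            resid = y - A @ th
            log_joint[i, j] = (-0.5 * resid @ resid / sigma2
                               - 0.5 * 8 * np.log(2 * np.pi * sigma2)
                               - 0.5 * th @ th / 0.5
                               - np.log(2 * np.pi * 0.5))
    m = log_joint.max()
    dx = t[1] - t[0]
    log_ev = m + np.log(np.sum(np.exp(log_joint - m)) * dx * dx)
    assert result.free_energy <= log_ev + 1e-3


# ---------------------------------------------------------------------------
# fit_channel
# ---------------------------------------------------------------------------

def test_fit_channel_self_consistency(base_params, base_obs, grid):
    observed = cmc.predict_psd(base_params, base_obs, grid)
    result = vl.fit_channel(observed)
    prior = vl.default_prior()
    sd = np.sqrt(np.diag(result.posterior.covariance))
    shift = np.abs(result.posterior.mean - prior.mean)
    assert np.all(shift <= 2 * sd)
    # the mean-shift part of the KL is small; the covariance-contraction
    # part is substantial for noiseless data and not asserted
    diff = result.posterior.mean - prior.mean
    mean_kl = 0.5 * diff @ np.linalg.solve(prior.covariance, diff)
    assert mean_kl < 0.5


def test_fit_channel_recovers_shifted_couplings(grid):
    """Known +0.4 shifts on three coupling parameters recovered within 2
    posterior SDs in >= 80% of seeded replicates."""
    hits = 0
    n_rep = 10
    shift_idx = [0, 1, 4]
    for seed in range(n_rep):
        rng = np.random.default_rng(1000 + seed)
        vec = cmc.pack_parameters(cmc.CMCParameters(),
                                  cmc.ObservationParameters())
        vec[shift_idx] += 0.4
        p, o = cmc.unpack_parameters(vec)
        observed = np.exp(np.log(cmc.predict_psd(p, o, grid))
                          + rng.normal(0, 0.05, grid.size))
        result = vl.fit_channel(observed)
        sd = np.sqrt(np.diag(result.posterior.covariance))
        ok = all(abs(result.posterior.mean[i] - vec[i]) <= 2 * sd[i]
                 for i in shift_idx)
        hits += ok
    assert hits >= 0.8 * n_rep


def test_fit_trajectory_monotone(small_cohort_fits):
    for fr in small_cohort_fits[:5]:
        traj = np.asarray(fr.f_trajectory)
        assert np.all(np.diff(traj) >= -1e-9)


def test_fit_channel_rejects_nonpositive(grid):
    bad = np.ones(60)
    bad[10] = 0.0
    with pytest.raises(ValueError):
        vl.fit_channel(bad)


def test_fit_channel_unstable_prior_error(grid, base_psd):
    mean = vl.default_prior().mean.copy()
    mean[2] += 8.0  # destabilize the dp->ii coupling massively
    mean[5] += 8.0
    prior = vl.PriorSpec(mean=mean,
                         covariance=vl.default_prior().covariance)
    with pytest.raises(cmc.InstabilityError):
        vl.fit_channel(base_psd, prior=prior)


# ---------------------------------------------------------------------------
# fit quality
# ---------------------------------------------------------------------------

def test_mse_identical_zero(base_psd):
    assert vl.fit_quality_mse(base_psd, base_psd) == 0.0


def test_mse_hand_computed():
    observed = np.full(60, 1.0 / 60.0)
    predicted = observed.copy()
    predicted[0] += 0.1
    predicted[1] -= 0.1
    # normalization leaves predicted sum unchanged, so residuals are +-0.1
    expected = (0.1**2 + 0.1**2) / 60.0
    assert vl.fit_quality_mse(observed * 7.0, predicted * 7.0) == \
        pytest.approx(expected, rel=1e-10)


def test_poor_fit_threshold():
    assert vl.POOR_FIT_MSE == 0.05
    assert 0.051 > vl.POOR_FIT_MSE
    assert not 0.049 > vl.POOR_FIT_MSE


def test_mse_zero_power_error():
    with pytest.raises(ValueError):
        vl.fit_quality_mse(np.zeros(60), np.ones(60))


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def test_compare_models_delta_five():
    p = vl.compare_models([5.0, 0.0])
    assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(-5.0)), rel=1e-12)
    assert p[0] > 0.99


def test_compare_models_uniform():
    np.testing.assert_allclose(vl.compare_models([2.0, 2.0, 2.0]), 1 / 3,
                               rtol=1e-12)


def test_compare_models_closed_form():
    F = np.array([0.0, -5.0, -10.0])
    expected = np.exp(F) / np.exp(F).sum()
    np.testing.assert_allclose(vl.compare_models(F), expected, rtol=1e-12)


def test_compare_models_sum_and_equivariance():
    rng = np.random.default_rng(8)
    F = rng.normal(0, 10, 6)
    p = vl.compare_models(F)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    perm = rng.permutation(6)
    np.testing.assert_allclose(vl.compare_models(F[perm]), p[perm],
                               rtol=1e-10)


def test_compare_models_empty_error():
    with pytest.raises(ValueError):
        vl.compare_models([])
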