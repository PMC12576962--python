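"""Variational Laplace model inversion and free-energy model comparison.

Fits a nonlinear forward model g(θ) to data y under additive Gaussian noise
with a single unknown precision exp(λ), by maximising the variational free
energy

    F = accuracy − complexity
      = E_q[log p(y|θ)] − KL(q(θ)‖p(θ)) − KL(q(λ)‖p(λ)) ,

with a Gaussian approximate posterior q(θ) (the Laplace assumption).  The
optimizer is Gauss–Newton ascent on F with Levenberg-style adaptive step
regularization; the forward-map Jacobian is obtained by finite differences.
F is a lower bound on log model evidence, so fitted models can be compared
directly through their free energies (softmax over F gives posterior model
probabilities under flat model priors).

For channel spectra the forward map is the canonical-microcircuit PSD
prediction and residuals are defined on log power, equalising weight across
the 1/f dynamic range of iEEG spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import cmc

__all__ = [
    "PriorSpec",
    "Posterior",
    "FitResult",
    "FitConfig",
    "default_prior",
    "log_likelihood",
    "free_energy",
    "free_energy_terms",
    "gaussian_kl",
    "fit_model",
    "fit_channel",
    "fit_quality_mse",
    "compare_models",
]


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior over free parameters plus a noise hyperprior.

    ``covariance`` must be symmetric positive definite (a 1-D array is
    interpreted as a diagonal).  The hyperprior is over λ = log precision
    of the observation noise.
    """

    mean: np.ndarray
    covariance: np.ndarray
    noise_log_precision_mean: float = 4.0
    noise_log_precision_variance: float = 16.0

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.ndim == 1:
            cov = np.diag(cov)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("prior covariance shape inconsistent with mean")
        if not np.allclose(cov, cov.T):
            raise ValueError("prior covariance must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if np.min(eigvals) <= 0:
            raise ValueError("prior covariance must be positive definite")
        if self.noise_log_precision_variance <= 0:
            raise ValueError("noise hyperprior variance must be positive")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    @property
    def size(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class Posterior:
    """Gaussian posterior over free parameters."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (mean.size, mean.size):
            raise ValueError("posterior covariance shape inconsistent")
        if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(cov))):
            raise ValueError("posterior must be finite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", 0.5 * (cov + cov.T))


@dataclass(frozen=True)
class FitResult:
    posterior: Posterior
    free_energy: float
    accuracy: float
    complexity: float
    predicted: np.ndarray
    mse: float
    iterations: int
    converged: bool
    log_precision: float
    f_trajectory: tuple = ()


@dataclass(frozen=True)
class FitConfig:
    max_iterations: int = 64
    convergence_tolerance: float = 0.01
    #: number of consecutive small-|ΔF| iterations required for convergence
    convergence_streak: int = 3
    initial_damping: float = 1.0
    fd_step: float = 1e-4
    #: fit residuals on log power (the default for spectra)
    log_transform: bool = True
    #: when set, the noise log-precision λ is held fixed at this value
    fixed_log_precision: float | None = None

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be positive")


def default_prior() -> PriorSpec:
    """Weakly-informative shrinkage prior over the 19 channel parameters.

    Variances: 1/8 for coupling log-scalings, 1/16 for time-constant
    log-scalings, 1/2 for observation parameters (with a tighter 1/16 on
    the innovation power-law exponent, which is box-constrained in [0, 2]).
    """
    mean = cmc.pack_parameters(cmc.CMCParameters(),
                               cmc.ObservationParameters())
    variances = np.concatenate([
        np.full(10, 1.0 / 8.0),     # couplings and self-modulation
        np.full(4, 1.0 / 16.0),     # time constants
        np.array([0.5, 0.5, 1.0 / 16.0, 0.5, 0.5]),  # observation
    ])
    return PriorSpec(mean=mean, covariance=variances)


def log_likelihood(observed: np.ndarray, predicted: np.ndarray,
                   log_precision: float,
                   log_transform: bool = True) -> float:
    """Gaussian log-density of the (log-)spectral residuals.

    Residuals are log(observed) − log(predicted) when ``log_transform`` is
    set; the iid precision is exp(log_precision).
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted grids must match")
    if log_transform:
        if np.any(observed <= 0) or np.any(predicted <= 0):
            raise ValueError("power must be strictly positive to log-transform")
        resid = np.log(observed) - np.log(predicted)
    else:
        resid = observed - predicted
    n = resid.size
    return float(-0.5 * n * np.log(2.0 * np.pi) + 0.5 * n * log_precision
                 - 0.5 * np.exp(log_precision) * resid @ resid)


def gaussian_kl(mean_q: np.ndarray, cov_q: np.ndarray, mean_p: np.ndarray,
                cov_p: np.ndarray) -> float:
    """KL(q‖p) between two multivariate Gaussians (closed form)."""
    d = mean_q.size
    chol_p = np.linalg.cholesky(cov_p)
    solve_p = np.linalg.solve
    diff = mean_p - mean_q
    inv_p_cov_q = solve_p(cov_p, cov_q)
    maha = diff @ solve_p(cov_p, diff)
    logdet_p = 2.0 * np.sum(np.log(np.diag(chol_p)))
    sign, logdet_q = np.linalg.slogdet(cov_q)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior covariance not PD in KL")
    return float(0.5 * (np.trace(inv_p_cov_q) + maha - d
                        + logdet_p - logdet_q))


def _finite_difference_jacobian(forward: Callable[[np.ndarray], np.ndarray],
                                theta: np.ndarray, f0: np.ndarray,
                                step: float) -> np.ndarray:
    J = np.empty((f0.size, theta.size))
    for j in range(theta.size):
        tp = theta.copy()
        tp[j] += step
        J[:, j] = (forward(tp) - f0) / step
    return J


def free_energy_terms(resid: np.ndarray, jac: np.ndarray,
                      cov_q: np.ndarray, mean_q: np.ndarray,
                      prior: PriorSpec, log_precision: float,
                      include_noise_kl: bool = True):
    """Accuracy, complexity and F for given posterior and residuals.

    Accuracy is the expected log-likelihood under q, evaluated at the
    posterior mean with the Gauss–Newton curvature correction
    −½·exp(λ)·tr(Σ_q JᵀJ).  Complexity is KL(q‖p) over θ plus, when the
    noise precision is estimated, the KL of the Gaussian λ-posterior implied
    by the curvature of the λ-objective.
    """
    n = resid.size
    precision = np.exp(log_precision)
    expected_sq = resid @ resid + np.trace(cov_q @ (jac.T @ jac))
    accuracy = (-0.5 * n * np.log(2.0 * np.pi) + 0.5 * n * log_precision
                - 0.5 * precision * expected_sq)
    complexity = gaussian_kl(mean_q, cov_q, prior.mean, prior.covariance)
    if include_noise_kl:
        # λ-posterior: Laplace approximation around the current estimate
        lam_post_var = 1.0 / (1.0 / prior.noise_log_precision_variance
                              + 0.5 * precision * expected_sq)
        complexity += gaussian_kl(
            np.array([log_precision]), np.array([[lam_post_var]]),
            np.array([prior.noise_log_precision_mean]),
            np.array([[prior.noise_log_precision_variance]]))
    return float(accuracy), float(complexity)


def free_energy(posterior: Posterior, prior: PriorSpec, observed: np.ndarray,
                forward: Callable[[np.ndarray], np.ndarray],
                log_precision: float | None = None,
                include_noise_kl: bool = False,
                fd_step: float = 1e-4):
    """Free-energy decomposition for a given posterior and forward map.

    Returns ``(accuracy, complexity, F)`` with F = accuracy − complexity;
    complexity is a KL divergence and therefore non-negative.  When
    ``log_precision`` is None the noise hyperprior mean is used.
    """
    y = np.asarray(observed, dtype=float)
    lam = prior.noise_log_precision_mean if log_precision is None \
        else log_precision
    f = forward(posterior.mean)
    resid = y - f
    jac = _finite_difference_jacobian(forward, posterior.mean.copy(), f,
                                      fd_step)
    acc, comp = free_energy_terms(resid, jac, posterior.covariance,
                                  posterior.mean, prior, lam,
                                  include_noise_kl=include_noise_kl)
    return acc, comp, acc - comp


def _update_log_precision(prior: PriorSpec, expected_sq: float,
                          n: int, lam: float) -> float:
    """MAP update of λ by Newton on n/2·λ − exp(λ)E/2 − (λ−λ0)²/(2v0)."""
    lam0 = prior.noise_log_precision_mean
    v0 = prior.noise_log_precision_variance
    for _ in range(50):
        grad = 0.5 * n - 0.5 * np.exp(lam) * expected_sq - (lam - lam0) / v0
        hess = -0.5 * np.exp(lam) * expected_sq - 1.0 / v0
        step = -grad / hess
        lam += np.clip(step, -4.0, 4.0)
        if abs(step) < 1e-10:
            break
    return float(lam)


def fit_model(observed: np.ndarray,
              forward: Callable[[np.ndarray], np.ndarray],
              prior: PriorSpec,
              config: FitConfig = FitConfig()) -> FitResult:
    """Gauss–Newton variational Laplace for a generic forward map.

    ``forward`` maps a parameter vector to the model prediction in data
    space (already log-transformed if the residuals are on log power).
    The accepted-iteration free energy trajectory is monotone
    non-decreasing by construction.
    """
    y = np.asarray(observed, dtype=float)
    prior_prec = np.linalg.inv(prior.covariance)
    mu = prior.mean.copy()
    lam = (prior.noise_log_precision_mean
           if config.fixed_log_precision is None
           else config.fixed_log_precision)

    def evaluate(mu_c, lam_c, jac=None):
        f = forward(mu_c)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError("non-finite forward prediction")
        resid = y - f
        if jac is None:
            jac = _finite_difference_jacobian(forward, mu_c, f, config.fd_step)
        if not np.all(np.isfinite(jac)):
            raise FloatingPointError("non-finite gradient of forward map")
        precision = np.exp(lam_c)
        hess = precision * jac.T @ jac + prior_prec
        cov_q = np.linalg.inv(hess)
        acc, comp = free_energy_terms(
            resid, jac, cov_q, mu_c, prior, lam_c,
            include_noise_kl=config.fixed_log_precision is None)
        return f, resid, jac, cov_q, acc, comp

    try:
        f, resid, jac, cov_q, acc, comp = evaluate(mu, lam)
    except (cmc.InstabilityError, cmc.FixedPointError) as exc:
        raise cmc.InstabilityError(
            "forward model unstable at the prior mean; adjust the prior "
            f"({exc})") from exc

    F = acc - comp
    trajectory = [F]
    damping = config.initial_damping
    streak = 0
    converged = False
    iterations = 0

    for iterations in range(1, config.max_iterations + 1):
        # EM update of the noise precision at the current posterior
        if config.fixed_log_precision is None:
            expected_sq = resid @ resid + np.trace(cov_q @ (jac.T @ jac))
            lam_new = _update_log_precision(prior, expected_sq, y.size, lam)
            _, _, _, cov_try, acc_try, comp_try = evaluate(mu, lam_new, jac)
            if acc_try - comp_try >= F - 1e-12:
                lam, cov_q, acc, comp = lam_new, cov_try, acc_try, comp_try
                F = acc - comp

        precision = np.exp(lam)
        grad = precision * jac.T @ resid - prior_prec @ (mu - prior.mean)
        hess = precision * jac.T @ jac + prior_prec

        accepted = False
        for _ in range(8):
            reg = hess + damping * np.diag(np.diag(hess))
            try:
                step = np.linalg.solve(reg, grad)
            except np.linalg.LinAlgError:
                damping *= 4.0
                continue
            try:
                cand = evaluate(mu + step, lam)
            except (cmc.InstabilityError, cmc.FixedPointError,
                    FloatingPointError, np.linalg.LinAlgError):
                damping *= 4.0
                continue
            F_new = cand[4] - cand[5]
            if np.isfinite(F_new) and F_new > F:
                mu = mu + step
                f, resid, jac, cov_q, acc, comp = cand
                dF = F_new - F
                F = F_new
                trajectory.append(F)
                damping = max(damping / 2.0, 1e-8)
                accepted = True
                break
            damping *= 4.0
        if not accepted:
            converged = True
            break
        streak = streak + 1 if dF < config.convergence_tolerance else 0
        if streak >= config.convergence_streak:
            converged = True
            break

    mse = fit_quality_mse(np.exp(y), np.exp(f)) if config.log_transform \
        else float(np.mean((y - f) ** 2))
    return FitResult(
        posterior=Posterior(mu, cov_q), free_energy=float(F),
        accuracy=float(acc), complexity=float(comp),
        predicted=np.exp(f) if config.log_transform else f,
        mse=mse, iterations=iterations, converged=converged,
        log_precision=float(lam), f_trajectory=tuple(trajectory))


def fit_channel(observed: np.ndarray, prior: PriorSpec | None = None,
                config: FitConfig = FitConfig(),
                grid: np.ndarray | None = None) -> FitResult:
    """Fit the CMC spectral model to one observed channel PSD.

    ``observed`` is the power on the frequency grid (strictly positive);
    residuals are taken on log power.
    """
    grid = cmc.default_grid() if grid is None else cmc.validate_grid(grid)
    observed = np.asarray(observed, dtype=float)
    if observed.shape != grid.shape:
        raise ValueError("observed spectrum does not match the grid")
    if np.any(observed <= 0):
        raise ValueError("observed power must be strictly positive")
    prior = default_prior() if prior is None else prior

    def forward(theta):
        params, obs = cmc.unpack_parameters(theta)
        return np.log(cmc.predict_psd(params, obs, grid))

    return fit_model(np.log(observed), forward, prior, config)


def fit_quality_mse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared error between unit-total-power normalised spectra.

    Values above 0.05 flag a poor fit.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted grids must match")
    so, sp = observed.sum(), predicted.sum()
    if so <= 0 or sp <= 0:
        raise ValueError("cannot normalise a zero-power spectrum")
    return float(np.mean((observed / so - predicted / sp) ** 2))


POOR_FIT_MSE = 0.05


def compare_models(free_energies: Sequence[float]) -> np.ndarray:
    """Posterior model probabilities from free energies (softmax).

    Assumes flat priors over models; probabilities sum to one.
    """
    F = np.asarray(list(free_energies), dtype=float)
    if F.size == 0:
        raise ValueError("need at least one model free energy")
    z = np.exp(F - F.max())
    return z / z.sum()
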