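"""Parametric empirical Bayes: a Bayesian GLM over first-level posteriors.

The second level models the per-channel parameter estimates as

    θ_i ≈ X_i β + ε_i ,   ε_i ~ N(0, S_i + exp(−γ) I) ,

where θ_i and S_i are the first-level posterior mean and covariance of the
masked parameters, X_i the channel's design-matrix row (group mean plus
regressors), β the group-level effects and exp(−γ) the between-channel
residual variance (a single precision component).  β has a zero-mean
Gaussian prior; γ is estimated by maximising the second-level model
evidence, which also scores competing designs: more expressive designs pay
an automatic complexity penalty through the marginal likelihood.

The fitted hierarchy yields empirical priors — per-channel prior means
X_i β̂ with variance shrunk to the estimated between-channel residual —
under which first-level models can be re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from . import cmc, vl
from .receptors import DesignMatrix

__all__ = [
    "WithinSpec",
    "PEBModel",
    "PEBResult",
    "ModelComparison",
    "fit_peb",
    "model_search",
    "empirical_priors",
    "reestimate_with_empirical_priors",
]


@dataclass(frozen=True)
class WithinSpec:
    """Which first-level parameters receive group-level effects.

    Defaults to all 14 neuronal parameters; a couplings-only mask is
    ``WithinSpec(np.arange(10))``.
    """

    parameter_mask: np.ndarray = field(
        default_factory=lambda: np.arange(cmc.N_NEURONAL))

    def __post_init__(self):
        mask = np.asarray(self.parameter_mask, dtype=int)
        if mask.size == 0:
            raise ValueError("parameter mask must be non-empty")
        if mask.min() < 0 or mask.max() >= cmc.N_PARAMS:
            raise ValueError("parameter mask indices out of range")
        object.__setattr__(self, "parameter_mask", mask)


@dataclass(frozen=True)
class PEBModel:
    design: DesignMatrix
    within: WithinSpec = field(default_factory=WithinSpec)
    #: prior variance of each group-level effect (standardised regressors)
    beta_prior_variance: float = 1.0
    #: Gaussian prior over γ = log between-channel precision
    log_between_precision_mean: float = 4.0
    log_between_precision_variance: float = 4.0


@dataclass(frozen=True)
class PEBResult:
    group_betas: np.ndarray        # (1+k) × p
    beta_covariance: np.ndarray    # ((1+k)·p) × ((1+k)·p)
    second_level_free_energy: float
    log_between_precision: float
    model: PEBModel
    #: per-channel empirical prior means over the masked parameters
    empirical_prior_means: np.ndarray   # channels × p


@dataclass(frozen=True)
class ModelComparison:
    model_ids: tuple
    free_energies: np.ndarray
    posterior_probabilities: np.ndarray
    results: tuple = ()


def _first_level_moments(first_level: Sequence[vl.FitResult],
                         mask: np.ndarray):
    means = np.array([fr.posterior.mean[mask] for fr in first_level])
    covs = np.array([fr.posterior.covariance[np.ix_(mask, mask)]
                     for fr in first_level])
    return means, covs


def _evidence(X: np.ndarray, means: np.ndarray, eigvals: np.ndarray,
              eigvecs: np.ndarray, gamma: float, beta_var: float):
    """Log evidence of the stacked GLM and the β posterior at fixed γ.

    ``eigvals``/``eigvecs`` are the per-channel eigendecompositions of the
    first-level covariances S_i; V_i = S_i + exp(−γ)I shares eigenvectors.
    """
    n_ch, p = means.shape
    q = X.shape[1] * p
    sigma2 = np.exp(-gamma)
    d = eigvals + sigma2                       # channels × p
    # V_i^{-1} m_i and quadratic/logdet accumulators
    proj = np.einsum("cij,cj->ci", np.transpose(eigvecs, (0, 2, 1)), means)
    vinv_m = np.einsum("cij,cj->ci", eigvecs, proj / d)
    quad = float(np.sum(proj**2 / d))
    logdet_v = float(np.sum(np.log(d)))
    precision = np.eye(q) / beta_var
    r = np.zeros(q)
    for i in range(n_ch):
        vinv = (eigvecs[i] / d[i]) @ eigvecs[i].T
        precision += np.kron(np.outer(X[i], X[i]), vinv)
        r += np.kron(X[i], vinv_m[i])
    cov_beta = np.linalg.inv(precision)
    mu_beta = cov_beta @ r
    sign, logdet_prec = np.linalg.slogdet(precision)
    log_ev = -0.5 * (n_ch * p * np.log(2.0 * np.pi) + logdet_v
                     + q * np.log(beta_var) + logdet_prec
                     + quad - r @ mu_beta)
    return float(log_ev), mu_beta, cov_beta


def fit_peb(first_level: Sequence[vl.FitResult],
            model: PEBModel) -> PEBResult:
    """Fit the second-level GLM by evidence maximisation.

    The group effects are obtained from a precision-weighted Bayesian
    regression of first-level posterior means (weighted by the full masked
    posterior covariances); the between-channel precision is optimised
    against the second-level evidence.  The returned free energy is the
    optimised log evidence plus the γ-prior density (a MAP-style bound,
    comparable across designs fitted to the same first level).
    """
    if len(first_level) < 2:
        raise ValueError("need at least two channels for a second level")
    X = model.design.values
    if X.shape[0] != len(first_level):
        raise ValueError("design rows must match the number of channels")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of collinear columns for the error message
        labels = model.design.column_labels
        bad = []
        for j in range(X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(labels[j])
        raise np.linalg.LinAlgError(
            f"rank-deficient design (collinear columns include: {bad})")

    mask = model.within.parameter_mask
    means, covs = _first_level_moments(first_level, mask)
    eigvals, eigvecs = np.linalg.eigh(covs)
    eigvals = np.clip(eigvals, 1e-12, None)

    g0 = model.log_between_precision_mean
    gv = model.log_between_precision_variance

    def neg_objective(gamma):
        log_ev, _, _ = _evidence(X, means, eigvals, eigvecs, gamma,
                                 model.beta_prior_variance)
        log_prior = -0.5 * (gamma - g0)**2 / gv \
            - 0.5 * np.log(2.0 * np.pi * gv)
        return -(log_ev + log_prior)

    opt = minimize_scalar(neg_objective, bounds=(g0 - 10.0, g0 + 10.0),
                          method="bounded",
                          options={"xatol": 1e-3})
    gamma = float(opt.x)
    log_ev, mu_beta, cov_beta = _evidence(X, means, eigvals, eigvecs, gamma,
                                          model.beta_prior_variance)
    F = -float(opt.fun)
    betas = mu_beta.reshape(X.shape[1], mask.size)
    empirical = X @ betas
    return PEBResult(group_betas=betas, beta_covariance=cov_beta,
                     second_level_free_energy=F,
                     log_between_precision=gamma, model=model,
                     empirical_prior_means=empirical)


def model_search(first_level: Sequence[vl.FitResult],
                 designs: Sequence[DesignMatrix],
                 model_ids: Sequence[str] | None = None,
                 **model_kwargs) -> ModelComparison:
    """Fit one PEB per design and compare second-level free energies."""
    if len(designs) < 2:
        raise ValueError("need at least two designs to compare")
    if model_ids is None:
        model_ids = ["+".join(d.column_labels[1:]) or "mean-only"
                     for d in designs]
    results = [fit_peb(first_level, PEBModel(design=d, **model_kwargs))
               for d in designs]
    F = np.array([r.second_level_free_energy for r in results])
    return ModelComparison(tuple(model_ids), F, vl.compare_models(F),
                           tuple(results))


def empirical_priors(peb: PEBResult,
                     base_prior: vl.PriorSpec | None = None
                     ) -> list[vl.PriorSpec]:
    """Per-channel empirical priors implied by the fitted hierarchy.

    The prior mean over masked parameters is the design prediction X_i β̂;
    the prior variance over those parameters is the original first-level
    prior variance shrunk to (at most) the estimated between-channel
    residual variance exp(−γ̂).  All other parameters keep the base prior.
    """
    base = vl.default_prior() if base_prior is None else base_prior
    mask = peb.model.within.parameter_mask
    resid_var = np.exp(-peb.log_between_precision)
    priors = []
    for pred in peb.empirical_prior_means:
        mean = base.mean.copy()
        mean[mask] = mean[mask] + pred
        cov = base.covariance.copy()
        for idx in mask:
            cov[idx, idx] = min(cov[idx, idx], resid_var)
        priors.append(vl.PriorSpec(
            mean=mean, covariance=cov,
            noise_log_precision_mean=base.noise_log_precision_mean,
            noise_log_precision_variance=base.noise_log_precision_variance))
    return priors


def reestimate_with_empirical_priors(
        observed_spectra: Sequence[np.ndarray], peb: PEBResult,
        config: vl.FitConfig = vl.FitConfig(),
        base_prior: vl.PriorSpec | None = None,
        grid: np.ndarray | None = None) -> list[vl.FitResult]:
    """Refit every channel under the hierarchy's empirical priors."""
    if len(observed_spectra) != peb.empirical_prior_means.shape[0]:
        raise ValueError("one observed spectrum per channel is required")
    priors = empirical_priors(peb, base_prior)
    return [vl.fit_channel(obs, prior=prior, config=config, grid=grid)
            for obs, prior in zip(observed_spectra, priors)]
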