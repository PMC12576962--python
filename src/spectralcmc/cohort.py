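"""Synthetic cohorts with the full generative structure the analysis assumes.

The generator runs the hierarchical model forwards: a receptor-density
table with low-rank inter-receptor correlation and strongly correlated
cortical layers; channel-level microcircuit parameters drawn as

    θ_i = prior mean + X_i B + ε_i ,  ε_i ~ N(0, between_channel_sd² I) ,

with X the design matrix built from the table's own principal-component
scores and B the true group effects; and observed spectra as the forward-
predicted PSD with lognormal observation noise.  Every stage of the
pipeline can therefore be tested against known ground truth without any
external data.

Defaults emulate the reference datasets' scale: 15 receptors, three
cortical layers with inter-layer correlation ≈ 0.85, four latent receptor
gradients, effect sizes of 0.2 log-units on coupling parameters and 0.1
log-units of between-channel and observation noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cmc
from .receptors import (DesignMatrix, ReceptorTable, average_layers,
                        build_design_matrix, map_channels_to_regions,
                        normalize_columns, principal_components)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_receptor_table",
    "generate_channel_parameters",
    "generate_spectra",
    "generate_cohort",
]

#: relative scale of successive latent receptor gradients
_LATENT_SCALES = (1.0, 0.7, 0.5, 0.35, 0.25, 0.18)

#: spectrally identifiable coupling directions (indices into the neuronal
#: parameter vector).  The observed output sees each inhibitory feedback
#: loop only through its round-trip gain, so loop pairs (ss↔ii, dp↔ii)
#: are assigned equal effects; sp→ss and the non-interneuron self-gains
#: have near-zero spectral sensitivity at the operating point and never
#: receive true effects.
_EFFECT_DIRECTIONS = ((0,), (1, 4), (2, 5))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a synthetic cohort."""

    n_regions: int = 40
    channels_per_region: int = 5
    n_receptors: int = 15
    latent_dim: int = 4
    n_effect_regressors: int = 4
    #: magnitude of true group effects (log-units on coupling parameters)
    effect_size: float = 0.2
    #: couplings each regressor acts on
    effects_per_regressor: int = 3
    between_channel_sd: float = 0.1
    observation_noise_sd: float = 0.1
    #: target inter-layer correlation of receptor densities
    interlayer_correlation: float = 0.85


@dataclass(frozen=True)
class GroundTruth:
    true_group_betas: np.ndarray          # (1+k) × p_masked
    true_channel_params: np.ndarray       # channels × N_PARAMS
    between_channel_sd: float
    observation_noise_sd: float
    master_seed: int


@dataclass(frozen=True)
class SyntheticCohort:
    receptor_table: ReceptorTable
    channel_map: dict
    channel_ids: tuple
    spectra: np.ndarray                   # channels × len(grid)
    grid: np.ndarray
    design: DesignMatrix                  # the true PC design (mean + PCs)
    truth: GroundTruth

    @property
    def channel_regions(self) -> list:
        return [self.channel_map[c] for c in self.channel_ids]


def generate_receptor_table(n_regions: int = 44, n_receptors: int = 15,
                            latent_dim: int = 4, seed: int = 0,
                            interlayer_correlation: float = 0.85
                            ) -> ReceptorTable:
    """Receptor densities with low-rank regional structure and three
    strongly correlated layers.

    Regional latent factors times receptor loadings give a shared profile;
    each layer adds independent noise sized so the expected inter-layer
    correlation matches ``interlayer_correlation``.  A positive affine map
    per receptor converts z-scale profiles to densities in fmol/mg protein.
    """
    if latent_dim > n_receptors:
        raise ValueError("latent_dim cannot exceed n_receptors")
    if latent_dim < 1 or n_regions < 2:
        raise ValueError("need latent_dim >= 1 and n_regions >= 2")
    rng = np.random.default_rng(seed)
    scales = np.array([_LATENT_SCALES[i % len(_LATENT_SCALES)]
                       * 0.9 ** (i // len(_LATENT_SCALES))
                       for i in range(latent_dim)])
    factors = rng.standard_normal((n_regions, latent_dim)) * scales
    loadings = rng.standard_normal((latent_dim, n_receptors))
    shared = factors @ loadings
    shared = (shared - shared.mean(0)) / shared.std(0)
    # layer noise for correlation r: var_noise = var_shared * (1/r − 1)
    noise_sd = np.sqrt(1.0 / interlayer_correlation - 1.0)
    layers = np.stack([
        shared + noise_sd * rng.standard_normal(shared.shape)
        for _ in range(3)], axis=2)
    # per-receptor positive affine transform: mean 20–60, spread ~15% of mean
    base = rng.uniform(20.0, 60.0, n_receptors)
    spread = 0.15 * base
    density = base[None, :, None] + spread[None, :, None] * layers
    density = np.clip(density, 0.1, None)
    regions = tuple(f"region{r:02d}" for r in range(n_regions))
    receptor_names = tuple(f"receptor{i:02d}" for i in range(n_receptors))
    return ReceptorTable(regions, receptor_names, density)


def _true_betas(config: CohortConfig, rng: np.random.Generator,
                n_params: int) -> np.ndarray:
    """Sparse ±effect_size group effects of each regressor on couplings.

    ``effect_size`` is the shift in log-units per standard deviation of the
    regressor; the caller rescales to the regressor's raw scale.  Effects
    land on ``effects_per_regressor`` of the identifiable coupling
    directions (see ``_EFFECT_DIRECTIONS``), with equal betas on both
    members of a degenerate loop pair.
    """
    k = config.n_effect_regressors
    betas = np.zeros((1 + k, n_params))
    n_dir = len(_EFFECT_DIRECTIONS)
    n_eff = min(config.effects_per_regressor, n_dir)
    for j in range(1, 1 + k):
        directions = rng.choice(n_dir, size=n_eff, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_eff)
        for d, sign in zip(directions, signs):
            members = _EFFECT_DIRECTIONS[d]
            # the effect magnitude applies to the identified direction as a
            # whole; loop pairs share it equally between their members
            for idx in members:
                betas[j, idx] = config.effect_size * sign / len(members)
    return betas


def generate_channel_parameters(design: DesignMatrix, betas: np.ndarray,
                                between_channel_sd: float, seed: int,
                                max_reject_fraction: float = 0.5
                                ) -> np.ndarray:
    """Channel parameter vectors from the second-level generative model.

    params_i = prior mean + X_i·betas + N(0, between_channel_sd²) over the
    masked (neuronal) parameters; draws whose Jacobian is unstable are
    redrawn (the design contribution is kept, only the noise is redrawn).
    Raises if more than ``max_reject_fraction`` of channels needed redraws.
    """
    X = design.values
    if betas.shape[0] != X.shape[1]:
        raise ValueError("betas rows must match design columns")
    n_channels = X.shape[0]
    p = betas.shape[1]
    rng = np.random.default_rng(seed)
    base = cmc.pack_parameters(cmc.CMCParameters(),
                               cmc.ObservationParameters())
    params = np.tile(base, (n_channels, 1))
    systematic = X @ betas
    n_rejected = 0
    for i in range(n_channels):
        for attempt in range(50):
            noise = rng.normal(0.0, between_channel_sd, p)
            vec = base[:p] + systematic[i] + noise
            candidate = cmc.CMCParameters.from_vector(vec[:cmc.N_NEURONAL])
            if np.linalg.eigvals(
                    cmc.linearize(candidate)).real.max() < 0:
                params[i, :p] = vec
                break
            n_rejected += 1
        else:
            raise RuntimeError(
                f"channel {i}: no stable draw in 50 attempts; "
                "reduce effect sizes")
    if n_rejected > max_reject_fraction * n_channels:
        raise RuntimeError(
            f"{n_rejected} unstable draws for {n_channels} channels; "
            "reduce effect sizes")
    return params


def generate_spectra(channel_params: np.ndarray,
                     observation_noise_sd: float, seed: int,
                     grid: np.ndarray | None = None) -> np.ndarray:
    """Noisy forward spectra: log power = log PSD + N(0, noise_sd²)."""
    grid = cmc.default_grid() if grid is None else cmc.validate_grid(grid)
    rng = np.random.default_rng(seed)
    spectra = np.empty((channel_params.shape[0], grid.size))
    for i, vec in enumerate(channel_params):
        p, o = cmc.unpack_parameters(vec)
        psd = cmc.predict_psd(p, o, grid)
        spectra[i] = np.exp(np.log(psd)
                            + rng.normal(0.0, observation_noise_sd,
                                         grid.size))
    return spectra


def generate_cohort(config: CohortConfig = CohortConfig(),
                    seed: int = 0) -> SyntheticCohort:
    """Compose receptor table, true design, parameters and spectra.

    The true design is the group-mean column plus the first
    ``n_effect_regressors`` principal-component scores of the cohort's own
    receptor matrix, mapped to channels — exactly the regressors the
    recovery analysis will later rebuild from the released files.
    """
    table_seed, beta_seed, params_seed, noise_seed = (
        int(s) % (2**31 - 1)
        for s in np.random.SeedSequence(seed).generate_state(4))
    rng_beta = np.random.default_rng(beta_seed)

    table = generate_receptor_table(
        config.n_regions, config.n_receptors, config.latent_dim,
        seed=table_seed,
        interlayer_correlation=config.interlayer_correlation)

    matrix = normalize_columns(average_layers(table), table.region_labels,
                               table.receptor_labels)
    basis = principal_components(matrix, config.n_effect_regressors)

    channel_ids = tuple(
        f"{region}_ch{c}" for region in table.region_labels
        for c in range(config.channels_per_region))
    channel_map = {cid: cid.rsplit("_ch", 1)[0] for cid in channel_ids}
    channel_scores = map_channels_to_regions(
        channel_ids, channel_map, table.region_labels, basis.scores)
    pc_labels = [f"PC{j + 1}" for j in range(config.n_effect_regressors)]
    design = build_design_matrix(channel_scores, channel_ids, pc_labels)

    betas = _true_betas(config, rng_beta, cmc.N_NEURONAL)
    # effect_size is defined per standard deviation of a regressor, so the
    # raw-score betas are scaled by 1/sd — PC scores are not unit variance
    score_sd = basis.scores.std(axis=0, ddof=1)
    betas[1:] /= score_sd[:, None]
    params = generate_channel_parameters(design, betas,
                                         config.between_channel_sd,
                                         seed=params_seed)
    grid = cmc.default_grid()
    spectra = generate_spectra(params, config.observation_noise_sd,
                               seed=noise_seed, grid=grid)
    truth = GroundTruth(true_group_betas=betas, true_channel_params=params,
                        between_channel_sd=config.between_channel_sd,
                        observation_noise_sd=config.observation_noise_sd,
                        master_seed=seed)
    return SyntheticCohort(receptor_table=table, channel_map=channel_map,
                           channel_ids=channel_ids, spectra=spectra,
                           grid=grid, design=design, truth=truth)
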