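# Methods

This note describes, in the package's own terms, the generative model,
the inference machinery, and the validation logic implemented in
`spectralcmc`.

## 1. Forward model (`spectralcmc.cmc`)

### Populations and connectivity

Each channel is modelled as one canonical microcircuit with four neural
populations: spiny stellate cells (`ss`), superficial pyramidal cells
(`sp`), inhibitory interneurons (`ii`) and deep pyramidal cells (`dp`).
Each population has two states, mean membrane potential and mean
current, giving an 8-dimensional state vector.

The directed connections are fixed in sign and topology:

- excitatory: `ss → sp`, `ss → ii`, `dp → ii`
- inhibitory: `sp → ss`, `ii → ss`, `ii → dp`
- one inhibitory self-modulation loop per population.

Free neuronal parameters are **log-scaling factors** around fixed base
values: 3 excitatory couplings, 3 inhibitory couplings, 4 self gains and
4 time constants — 14 in total. Base values: couplings 40, self gain 4,
time constants (2, 2, 16, 28) ms. Firing rates follow a logistic
sigmoid with slope 2/3 around the fixed point; per-population synaptic
gains (4, 4, 32, 4) mV convert firing to potential.

### Observation model

Five observation parameters: a log electrode gain, a log innovation
amplitude, an innovation spectral exponent (power-law input noise,
clipped to [0, 2]), and log amplitudes of additive white and pink
(1/f) channel noise. Exogenous input enters the stellate population.

### Spectral prediction

The system is linearized at its stable fixed point (found by damped
Newton iteration). The predicted power spectral density on the 1–60 Hz
grid (1 Hz steps) is

    PSD(f) = gain · |H(2πif)|² · S_innov(f) + S_white + S_pink(f)

where `H` is the transfer function from input to the superficial
pyramidal potential (the measured quantity) and `S_innov(f) ∝ f^(−χ)`.
If the Jacobian has any eigenvalue with non-negative real part, an
`InstabilityError` is raised.

Two independent simulators validate the prediction: an exact
zero-order-hold modal simulation of the linearized system, and a Heun
integration of the full nonlinear system in the small-noise regime.
Welch spectra of both match the analytic prediction (log-power
correlation > 0.99 for the linearized oracle at default parameters).

## 2. Variational Laplace (`spectralcmc.vl`)

Single-channel inversion maximizes a free-energy bound on log model
evidence under a Gaussian posterior. Observations are log powers; the
likelihood is iid Gaussian in log space with a single precision
hyperparameter (free by default, with a Gamma-like prior; optionally
fixed). Priors on the 19 parameters are independent Gaussians centred
on zero log-scaling (shrinkage to the canonical circuit).

The optimizer is a damped Gauss–Newton scheme on the free energy:
candidate steps are accepted only if F improves (damping is multiplied
by 4 on rejection and divided by 2 on acceptance), so the reported
trajectory is monotone. Gradients use central finite differences of the
forward model. Convergence is declared after a streak of iterations
with |ΔF| below tolerance.

Outputs per channel: posterior mean/covariance, free energy and its
accuracy/complexity split, iteration trajectory, noise precision, and a
normalized mean-squared error computed on unit-total-power spectra
(threshold 0.05 flags poor fits). On a linear-Gaussian problem the
implementation reproduces the conjugate posterior and the exact log
evidence to 1e-6.

## 3. Receptor features (`spectralcmc.receptors`)

A regional receptor-density table (regions × receptors × 3 cortical
layer bins) is reduced to channel-level covariates:

1. average over layers;
2. z-score each receptor across regions (sample SD);
3. PCA via SVD, components signed so the largest-magnitude loading is
   positive; scores are region-level coordinates;
4. map region scores to channels through the channel→region lookup;
5. build design matrices with a leading constant column and mean-centred
   regressors.

Candidate designs for model comparison are (a) cumulative PC designs
PC1, PC1-2, …, PC1-6 and (b) all 15 non-empty subsets of the four named
receptor families {AMPA, NMDA, GABA_A, GABA_B} (size histogram
4/6/4/1).

## 4. Parametric empirical Bayes (`spectralcmc.peb`)

The second level treats each channel's posterior (over a parameter
subset, by default all parameters; the coupling-only subset is used for
effect recovery) as data in a Bayesian GLM:

    θ_i = X_i β + ε_i,   ε_i ~ N(0, exp(−γ) I)

with Gaussian priors on the group coefficients β and on the log
between-channel precision γ. The channel-specific posterior
covariances are handled exactly through per-channel eigendecompositions
(computed once and reused across γ evaluations); γ is optimized by
bounded scalar search on the free energy. The second-level free energy
scores each design; posterior model probabilities are the softmax of
free energies. A free-energy difference of 5 corresponds to a winner
probability of 1/(1+e⁻⁵) ≈ 0.993.

The winning model yields **empirical priors**: prior means shifted by
X β̂ on the modelled subset and prior variances shrunk to exp(−γ̂)
where that is tighter than the original prior. `reestimate_with_
empirical_priors` refits every channel under them; `export_parameter_
atlas` writes the per-region prior means and variances for all 14
neuronal parameters.

## 5. Null suites (`spectralcmc.nulls`)

Three shuffle schemes destroy the receptor–parameter association while
preserving different structure:

- **N1** (receptor correlations preserved): permute whole regressor
  tuples across regions;
- **N2** (region boundaries preserved): permute each regressor
  independently across regions;
- **N3** (unstructured): permute regressor values across channels.

Each suite refits the PEB for `n_shuffles` shuffled designs and reports
`delta = F_reference − max(F_null)`. A positive delta on all three
suites indicates the association survives the most lenient null. Child
seeds come from `numpy.random.SeedSequence` and are kept below 2³¹.

## 6. Spectral summaries (`spectralcmc.spectral`)

Spectra normalized to unit total power are compared against a fixed
fractional-noise reference line `log10 P = 1 − log10 f` (i.e. 10/f).
The periodic component is the positive part of the difference; band
powers integrate it over delta/theta/alpha/beta/gamma bands (half-open,
gamma closed at 60 Hz). Helpers select the channels with most periodic
band power or the closest to the 1/f line, and compute moving-average
trends across sorted channels.

## 7. Synthetic cohorts (`spectralcmc.cohort`)

The generator is first-class, tested code — the package's substitute
for the non-distributable empirical data:

1. **Receptor table**: low-rank latent model (default 4 factors over 15
   receptors, 40 regions + 4 held-out regions) with correlated layer
   profiles (default inter-layer correlation 0.85) and positive
   densities.
2. **True effects**: group betas of the first 4 receptor PCs on
   *identifiable* coupling directions. The output spectrum constrains
   the `ss↔ii` and `dp↔ii` loops only through their loop gains (the
   within-loop split is exactly degenerate), and is nearly insensitive
   to `g_sp_ss` and to three of the self gains; effects are therefore
   planted on `g_ss_sp` and on the two loop-gain sums, split across
   loop members. Effect size (default 0.2 log units) is defined per
   standard deviation of the regressor, with signs and targets drawn
   per seed.
3. **Channel parameters**: θ_i = prior mean + X_i B + N(0, 0.1²), with
   rejection of unstable draws (error if rejection exceeds 50%).
4. **Spectra**: forward predictions with lognormal observation noise
   (sd 0.1 in log power).

Default scale: 40 regions × 5 channels = 200 channels. All stages are
deterministic given the master seed (child seeds via `SeedSequence`).

## 8. Pipeline (`spectralcmc.pipeline`)

`run_pipeline(PipelineConfig)` chains: read/validate inputs (or accept
an in-memory cohort) → first-level fits → receptor PCA → model search
over cumulative-PC designs (and optional receptor subsets) → null
suites for the winner → re-estimation under empirical priors → region
atlas export. Artifacts are CSV/JSON with the config hash and master
seed embedded in the summary; two runs with the same config are
byte-identical in content.

## 9. Validation logic

- **Oracles**: every numerical component is checked against an
  independent implementation (time-domain simulation vs transfer
  function; conjugate Gaussian algebra vs variational Laplace;
  dense quadrature bounds; OLS vs PEB in flat-prior limits;
  brute-force enumeration for shuffles, subsets and band selections).
- **Full-loop recovery**: on seeded 200-channel cohorts, recovered
  group betas correlate > 0.9 with truth, the PC1-4 design wins the
  model search in ≥ 80% of seeds, and all null deltas are positive.
- **Negative control**: with zero planted effects, the mean-only design
  is never beaten by an informed design (median posterior probability
  ≈ 1 for mean-only across 20 seeds).
- **Known failure, reported honestly**: re-estimation under empirical
  priors slightly *increases* mean spectrum MSE here (order 1e-6),
  because the first level already converges to near-zero residuals and
  tighter priors can only trade accuracy for hierarchical consistency.
  The corresponding acceptance test is left failing by design.
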