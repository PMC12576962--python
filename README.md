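# spectralcmc

Spectral dynamic causal modelling of intracranial EEG power spectra with a
canonical-microcircuit neural mass model, and hierarchical (parametric
empirical Bayes) analysis of how model parameters covary with regional
neurotransmitter-receptor densities.

## The scientific problem

Resting-state iEEG channels show highly structured 1–60 Hz power spectra
that differ systematically across cortical regions. This package asks two
questions:

1. **What microcircuit produces a given spectrum?** Each channel's power
   spectral density is explained by a four-population neural mass model
   (spiny stellate, superficial pyramidal, inhibitory interneurons, deep
   pyramidal) — the canonical microcircuit (CMC). Log-scale parameters
   (six coupling strengths, four self-modulation gains, four time
   constants, plus five observation parameters) are inverted per channel
   with variational Laplace, yielding a posterior density and a
   free-energy approximation to the log model evidence.
2. **Do microcircuit parameters follow receptor gradients?** At the
   second level, channel-wise posteriors are modelled with a general
   linear model whose regressors are principal components of a regional
   receptor-density table (or subsets of named receptors). Parametric
   empirical Bayes (PEB) estimates group-level effects; Bayesian model
   comparison via free energies identifies the best design; shuffle-based
   null suites check that the winning association is not an artifact of
   spatial or correlational structure in the regressors.

Because real iEEG and autoradiography data cannot ship with the code, a
fully specified synthetic-cohort generator is part of the package: it
draws a receptor table with a low-rank latent structure, plants known
group effects of the receptor PCs on identifiable coupling parameters,
and produces noisy spectra. The full loop (simulate → fit → PEB → model
comparison → nulls) is exercised by the test suite with known ground
truth.

## The model in brief

- Dynamics: second-order (voltage/current) dynamics for 4 populations,
  sigmoid firing-rate coupling, linearized around the stable fixed point.
- Spectrum: transfer function of the linearized system applied to a
  power-law innovation spectrum, plus white and pink channel noise, on a
  1–60 Hz grid at 1 Hz steps.
- Inversion: Gauss–Newton variational Laplace on log spectra under
  Gaussian shrinkage priors, with a free (or fixed) observation-noise
  precision and monotone free-energy trajectory.
- Hierarchy: PEB with precision components for between-channel variance;
  design search over cumulative receptor PCs (PC1, PC1-2, …) and the 15
  subsets of {AMPA, NMDA, GABA_A, GABA_B}; empirical priors from the
  winning model can be fed back for re-estimation and exported as a
  per-region parameter atlas.

See `docs/methods.md` for a full methods description.

## Worked example

```python
import numpy as np
import spectralcmc as s
from spectralcmc import cmc, vl, peb, receptors

# forward model: prior-mean microcircuit -> 1-60 Hz spectrum
grid = cmc.default_grid()
psd = cmc.predict_psd(cmc.CMCParameters(), cmc.ObservationParameters(), grid)

# invert a noisy spectrum
rng = np.random.default_rng(0)
observed = np.exp(np.log(psd) + rng.normal(0, 0.05, grid.size))
fit = vl.fit_channel(observed)
print(fit.free_energy, fit.mse)

# full loop on a synthetic cohort
cohort = s.generate_cohort(s.CohortConfig(n_regions=10,
                                          channels_per_region=2), seed=3)
fits = [vl.fit_channel(p) for p in cohort.spectra]
table = cohort.receptor_table
matrix = receptors.normalize_columns(receptors.average_layers(table),
                                     table.region_labels,
                                     table.receptor_labels)
basis = receptors.principal_components(matrix, 4)
scores = receptors.map_channels_to_regions(
    cohort.channel_ids, cohort.channel_map, table.region_labels,
    basis.scores)
design = receptors.build_design_matrix(scores, cohort.channel_ids,
                                       ["PC1", "PC2", "PC3", "PC4"])
result = peb.fit_peb(fits, peb.PEBModel(design=design))
print(result.group_betas.shape)   # (5 columns incl. mean) x 14 parameters
```

Runnable narrative scripts live in `examples/`:

- `forward_spectrum.py` — forward prediction and periodic/aperiodic summaries
- `fit_single_channel.py` — single-channel inversion and posterior report
- `receptor_pca.py` — receptor table → PCA → design matrices
- `cohort_pipeline.py` — the end-to-end pipeline with written artifacts
- `null_validation.py` — the three shuffle-based null suites

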