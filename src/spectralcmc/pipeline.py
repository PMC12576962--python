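"""File formats, configuration and end-to-end orchestration.

All tabular artifacts are plain CSV; run summaries are JSON.  The staged
pipeline goes: per-channel spectral fits → receptor features → second-level
model search (receptor subsets and cumulative principal components) → null
suites for the winning design → re-estimation under empirical priors →
export of the per-region parameter atlas.

This module is a thin orchestration layer over the library; the individual
stages are ordinary functions and can be run directly from Python.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cmc, vl
from .cohort import CohortConfig, SyntheticCohort, generate_cohort
from .nulls import SHUFFLE_SCHEMES, run_null_suite
from .peb import (PEBModel, PEBResult, WithinSpec, fit_peb, model_search,
                  reestimate_with_empirical_priors)
from .receptors import (ReceptorTable, LAYERS, average_layers,
                        build_design_matrix, enumerate_receptor_subsets,
                        map_channels_to_regions, normalize_columns,
                        principal_components)

__all__ = [
    "PipelineConfig",
    "read_spectra",
    "write_spectra",
    "read_receptor_table",
    "write_receptor_table",
    "read_channel_map",
    "write_channel_map",
    "write_cohort",
    "write_fit_results",
    "export_parameter_atlas",
    "run_pipeline",
]

logger = logging.getLogger("spectralcmc")


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, stage toggles and the knobs forwarded to each stage."""

    spectra_path: str = ""
    receptor_table_path: str = ""
    channel_map_path: str = ""
    output_dir: str = "pipeline_out"
    run_nulls: bool = True
    run_reestimation: bool = True
    n_pc_designs: int = 6
    n_shuffles: int = 40
    seed: int = 0
    max_iterations: int = 64
    #: candidate single receptors for the subset designs (must be columns
    #: of the receptor table); empty tuple skips the subset search
    candidate_receptors: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "candidate_receptors" in data:
            data["candidate_receptors"] = tuple(data["candidate_receptors"])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Spectra I/O: one row per channel: channel_id, region, then power per Hz
# ---------------------------------------------------------------------------

def write_spectra(path, channel_ids: Sequence[str],
                  regions: Sequence[str], spectra: np.ndarray,
                  grid: np.ndarray | None = None) -> None:
    grid = cmc.default_grid() if grid is None else cmc.validate_grid(grid)
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    cols = [f"power_{f:g}Hz" for f in grid]
    df = pd.DataFrame(spectra, columns=cols)
    df.insert(0, "region", list(regions))
    df.insert(0, "channel_id", list(channel_ids))
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra(path):
    """Read a spectra CSV; returns (channel_ids, regions, spectra, grid).

    The header declares the frequency grid (``power_<f>Hz`` columns) and is
    validated; non-positive powers are rejected with the offending channel
    named.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "channel_id" or df.columns[1] != "region":
        raise ValueError(
            "spectra file must start with 'channel_id,region' columns, got "
            f"{list(df.columns[:2])}")
    power_cols = list(df.columns[2:])
    freqs = []
    for col in power_cols:
        if not (col.startswith("power_") and col.endswith("Hz")):
            raise ValueError(f"malformed power column header: {col!r}")
        freqs.append(float(col[len("power_"):-len("Hz")]))
    grid = cmc.validate_grid(np.array(freqs))
    spectra = df[power_cols].to_numpy(dtype=float)
    bad = np.where(~np.all(spectra > 0, axis=1))[0]
    if bad.size:
        names = df["channel_id"].iloc[bad].tolist()
        raise ValueError(f"non-positive power in channel(s): {names}")
    return (df["channel_id"].tolist(), df["region"].tolist(), spectra, grid)


# ---------------------------------------------------------------------------
# Receptor table and channel map I/O
# ---------------------------------------------------------------------------

def write_receptor_table(path, table: ReceptorTable) -> None:
    table.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_receptor_table(path) -> ReceptorTable:
    """Read a long-format (region, receptor, layer, density) CSV.

    A wide region × receptor CSV (first column ``region``) is also
    accepted and interpreted as already layer-averaged: the three layers
    are filled with identical values.
    """
    df = pd.read_csv(path)
    if {"region", "receptor", "layer", "density"} <= set(df.columns):
        regions = list(dict.fromkeys(df["region"]))
        receptor_names = list(dict.fromkeys(df["receptor"]))
        density = np.full((len(regions), len(receptor_names), len(LAYERS)),
                          np.nan)
        r_idx = {r: i for i, r in enumerate(regions)}
        c_idx = {r: i for i, r in enumerate(receptor_names)}
        l_idx = {l: i for i, l in enumerate(LAYERS)}
        for row in df.itertuples(index=False):
            density[r_idx[row.region], c_idx[row.receptor],
                    l_idx[row.layer]] = row.density
        return ReceptorTable(regions, receptor_names, density)
    if df.columns[0] == "region":
        regions = df["region"].tolist()
        receptor_names = list(df.columns[1:])
        wide = df[receptor_names].to_numpy(dtype=float)
        density = np.repeat(wide[:, :, None], len(LAYERS), axis=2)
        return ReceptorTable(regions, receptor_names, density)
    raise ValueError("unrecognised receptor table format")


def write_channel_map(path, channel_map: dict) -> None:
    pd.DataFrame({"channel_id": list(channel_map),
                  "region": list(channel_map.values())}
                 ).to_csv(path, index=False)


def read_channel_map(path) -> dict:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["channel_id", "region"]:
        raise ValueError("channel map must have columns channel_id,region")
    return dict(zip(df["channel_id"], df["region"]))


def write_cohort(outdir, cohort: SyntheticCohort) -> dict:
    """Write a synthetic cohort in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spectra": outdir / "spectra.csv",
        "receptor_table": outdir / "receptor_table.csv",
        "channel_map": outdir / "channel_map.csv",
        "truth": outdir / "truth.json",
    }
    write_spectra(paths["spectra"], cohort.channel_ids,
                  cohort.channel_regions, cohort.spectra, cohort.grid)
    write_receptor_table(paths["receptor_table"], cohort.receptor_table)
    write_channel_map(paths["channel_map"], cohort.channel_map)
    truth = {
        "true_group_betas": cohort.truth.true_group_betas.tolist(),
        "between_channel_sd": cohort.truth.between_channel_sd,
        "observation_noise_sd": cohort.truth.observation_noise_sd,
        "master_seed": cohort.truth.master_seed,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return {k: str(v) for k, v in paths.items()}


def write_fit_results(path, channel_ids: Sequence[str],
                      fits: Sequence[vl.FitResult]) -> None:
    """One record per channel: posterior mean, posterior variance diagonal,
    free energy decomposition, MSE and convergence flag."""
    rows = []
    for cid, fr in zip(channel_ids, fits):
        row = {"channel_id": cid, "free_energy": fr.free_energy,
               "accuracy": fr.accuracy, "complexity": fr.complexity,
               "mse": fr.mse, "converged": fr.converged,
               "iterations": fr.iterations,
               "log_precision": fr.log_precision}
        for name, m, v in zip(cmc.PARAM_NAMES, fr.posterior.mean,
                              np.diag(fr.posterior.covariance)):
            row[f"mean_{name}"] = m
            row[f"var_{name}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def export_parameter_atlas(peb: PEBResult, regions: Sequence[str],
                           region_regressors: np.ndarray,
                           path=None) -> pd.DataFrame:
    """Per-region empirical prior means (and variances) for the 14
    neuronal parameters.

    ``region_regressors`` holds each region's regressor values on the same
    (uncentred) scale used to build the design; they are centred with the
    design's column means implicitly by passing centred values.
    """
    mask = peb.model.within.parameter_mask
    names = [cmc.PARAM_NAMES[i] for i in mask]
    X = np.hstack([np.ones((len(regions), 1)),
                   np.atleast_2d(region_regressors)])
    if X.shape[1] != peb.group_betas.shape[0]:
        raise ValueError("regressor count does not match fitted design")
    atlas_means = X @ peb.group_betas
    resid_var = float(np.exp(-peb.log_between_precision))
    df = pd.DataFrame(atlas_means, columns=[f"prior_mean_{n}" for n in names])
    df.insert(0, "region", list(regions))
    df["prior_variance"] = resid_var
    if path is not None:
        df.to_csv(path, index=False, float_format="%.10g")
    return df


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _fit_first_level(spectra, grid, config) -> list[vl.FitResult]:
    fit_cfg = vl.FitConfig(max_iterations=config.max_iterations)
    fits = []
    for i, psd in enumerate(spectra):
        fr = vl.fit_channel(psd, config=fit_cfg, grid=grid)
        logger.info("channel %d: F=%.2f mse=%.3g converged=%s",
                    i, fr.free_energy, fr.mse, fr.converged)
        fits.append(fr)
    return fits


def run_pipeline(config: PipelineConfig,
                 cohort: SyntheticCohort | None = None) -> dict:
    """Execute every stage and write all artifacts to the output directory.

    Inputs come either from the configured CSV paths or from an in-memory
    synthetic cohort.  Returns a summary dict (also written as JSON) with
    per-stage free energies, the winning design and the null deltas.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cohort is not None:
        channel_ids = list(cohort.channel_ids)
        regions_per_channel = cohort.channel_regions
        spectra, grid = cohort.spectra, cohort.grid
        table = cohort.receptor_table
        channel_map = cohort.channel_map
    else:
        channel_ids, regions_per_channel, spectra, grid = read_spectra(
            config.spectra_path)
        table = read_receptor_table(config.receptor_table_path)
        channel_map = read_channel_map(config.channel_map_path)

    summary: dict = {"config_hash": config.config_hash(),
                     "master_seed": config.seed,
                     "n_channels": len(channel_ids)}

    # stage 1: first-level fits
    fits = _fit_first_level(spectra, grid, config)
    write_fit_results(out / "first_level.csv", channel_ids, fits)
    summary["first_level"] = {
        "mean_free_energy": float(np.mean([f.free_energy for f in fits])),
        "n_poor_fits": int(sum(f.mse > vl.POOR_FIT_MSE for f in fits)),
        "n_converged": int(sum(f.converged for f in fits)),
    }

    # stage 2: receptor features
    matrix = normalize_columns(average_layers(table), table.region_labels,
                               table.receptor_labels)
    k_max = min(config.n_pc_designs,
                len(table.region_labels) - 1, len(table.receptor_labels))
    basis = principal_components(matrix, k_max)
    channel_scores = map_channels_to_regions(
        channel_ids, channel_map, table.region_labels, basis.scores)
    summary["pca_explained_fraction"] = basis.explained_fraction.tolist()

    # stage 3: model search over cumulative-PC designs (and, if configured,
    # receptor subsets)
    pc_labels = [f"PC{j + 1}" for j in range(k_max)]
    designs = [build_design_matrix(channel_scores[:, :j + 1], channel_ids,
                                   pc_labels[:j + 1])
               for j in range(k_max)]
    design_ids = [f"PC1-{j + 1}" if j else "PC1" for j in range(k_max)]
    comparison = model_search(fits, designs, design_ids)
    summary["pc_model_search"] = {
        "model_ids": list(comparison.model_ids),
        "free_energies": comparison.free_energies.tolist(),
        "posterior_probabilities":
            comparison.posterior_probabilities.tolist(),
    }
    winner_idx = int(np.argmax(comparison.free_energies))
    winner = comparison.results[winner_idx]
    summary["winning_design"] = comparison.model_ids[winner_idx]

    if config.candidate_receptors:
        col = {r: i for i, r in enumerate(table.receptor_labels)}
        missing = [r for r in config.candidate_receptors if r not in col]
        if missing:
            raise KeyError(f"candidate receptors not in table: {missing}")
        subsets = enumerate_receptor_subsets(config.candidate_receptors)
        sub_designs, sub_ids = [], []
        for subset in subsets:
            idx = [col[r] for r in subset]
            values = map_channels_to_regions(
                channel_ids, channel_map, table.region_labels,
                matrix.values[:, idx])
            sub_designs.append(
                build_design_matrix(values, channel_ids, subset))
            sub_ids.append("+".join(subset))
        sub_comparison = model_search(fits, sub_designs, sub_ids)
        summary["receptor_subset_search"] = {
            "model_ids": list(sub_comparison.model_ids),
            "free_energies": sub_comparison.free_energies.tolist(),
        }

    # stage 4: null suites for the winning design
    if config.run_nulls:
        n_regressors = winner.model.design.n_regressors
        region_values = basis.scores[:, :n_regressors]
        regressor_labels = winner.model.design.column_labels[1:]
        null_rows = []
        summary["nulls"] = {}
        for scheme in SHUFFLE_SCHEMES:
            suite = run_null_suite(
                fits, region_values, table.region_labels,
                regions_per_channel, regressor_labels, scheme,
                winner.second_level_free_energy,
                n_shuffles=config.n_shuffles, seed=config.seed)
            summary["nulls"][scheme] = {
                "delta": suite.delta,
                "best_null_F": float(np.max(suite.free_energies)),
                "median_null_F": float(np.median(suite.free_energies)),
            }
            for k, (s, F) in enumerate(zip(suite.seeds,
                                           suite.free_energies)):
                null_rows.append({"scheme": scheme, "shuffle_index": k,
                                  "seed": s, "free_energy": F})
        pd.DataFrame(null_rows).to_csv(out / "null_suites.csv", index=False)

    # stage 5: re-estimation under the winning empirical priors
    if config.run_reestimation:
        refits = reestimate_with_empirical_priors(
            spectra, winner,
            config=vl.FitConfig(max_iterations=config.max_iterations),
            grid=grid)
        write_fit_results(out / "reestimated.csv", channel_ids, refits)
        summary["reestimation"] = {
            "mean_mse_before": float(np.mean([f.mse for f in fits])),
            "mean_mse_after": float(np.mean([f.mse for f in refits])),
            "n_poor_fits_after": int(
                sum(f.mse > vl.POOR_FIT_MSE for f in refits)),
        }

    # stage 6: parameter atlas for the winning design
    n_regressors = winner.model.design.n_regressors
    centred_scores = basis.scores[:, :n_regressors] - channel_scores[
        :, :n_regressors].mean(axis=0)
    atlas = export_parameter_atlas(winner, table.region_labels,
                                   centred_scores, out / "atlas.csv")
    summary["atlas_regions"] = int(atlas.shape[0])

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
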