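"""Receptor-density processing: layer averaging, normalisation, PCA and
second-level design matrices.

Receptor autoradiography tables give densities (fmol/mg protein) per
(region, receptor, cortical layer).  Because densities correlate strongly
across the supragranular, granular and infragranular layers, the pipeline
works with the unweighted mean over layers, z-scored per receptor across
regions.  Principal components of the resulting region × receptor matrix
summarise co-varying receptor gradients and serve, mapped to channels, as
regressors of a hierarchical (second-level) GLM.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "LAYERS",
    "ReceptorTable",
    "ReceptorMatrix",
    "PCBasis",
    "DesignMatrix",
    "average_layers",
    "normalize_columns",
    "principal_components",
    "map_channels_to_regions",
    "build_design_matrix",
    "enumerate_receptor_subsets",
]

LAYERS = ("supragranular", "granular", "infragranular")


@dataclass(frozen=True)
class ReceptorTable:
    """Densities per (region, receptor, layer), fmol/mg protein.

    ``density`` has shape (n_regions, n_receptors, n_layers) with the layer
    axis ordered as :data:`LAYERS`.
    """

    region_labels: tuple
    receptor_labels: tuple
    density: np.ndarray

    def __post_init__(self):
        dens = np.asarray(self.density, dtype=float)
        expected = (len(self.region_labels), len(self.receptor_labels),
                    len(LAYERS))
        if dens.shape != expected:
            raise ValueError(
                f"density must have shape {expected}, got {dens.shape}")
        if np.any(dens[np.isfinite(dens)] < 0):
            raise ValueError("densities must be non-negative")
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        object.__setattr__(self, "receptor_labels",
                           tuple(self.receptor_labels))
        object.__setattr__(self, "density", dens)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: region, receptor, layer, density."""
        idx = pd.MultiIndex.from_product(
            [self.region_labels, self.receptor_labels, LAYERS],
            names=["region", "receptor", "layer"])
        return pd.DataFrame({"density": self.density.ravel()},
                            index=idx).reset_index()


@dataclass(frozen=True)
class ReceptorMatrix:
    """Layer-averaged, column-normalised region × receptor matrix."""

    region_labels: tuple
    receptor_labels: tuple
    values: np.ndarray            # z-scores, regions × receptors
    column_means: np.ndarray
    column_sds: np.ndarray

    def inverse_transform(self) -> np.ndarray:
        """Recover the raw layer-averaged densities."""
        return self.values * self.column_sds + self.column_means


@dataclass(frozen=True)
class PCBasis:
    """Principal components of the region × receptor matrix.

    ``loadings`` (receptors × components) are orthonormal; ``scores``
    (regions × components) are the regional gradients used as regressors.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_fraction: np.ndarray
    region_labels: tuple
    receptor_labels: tuple


@dataclass(frozen=True)
class DesignMatrix:
    """Second-level GLM design: a ones column plus mean-centred regressors."""

    values: np.ndarray
    column_labels: tuple
    channel_ids: tuple

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] != len(self.column_labels):
            raise ValueError("design shape inconsistent with labels")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "column_labels", tuple(self.column_labels))
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))

    @property
    def n_regressors(self) -> int:
        return len(self.column_labels) - 1


def average_layers(table: ReceptorTable,
                   allow_missing: bool = False) -> np.ndarray:
    """Unweighted mean density over the three cortical layers.

    Missing (NaN) layer entries are an error unless ``allow_missing`` is
    set, in which case the mean is over the available layers.
    """
    dens = table.density
    if np.any(np.isnan(dens)) and not allow_missing:
        bad = np.argwhere(np.isnan(dens))
        region, receptor, layer = bad[0]
        raise ValueError(
            "missing layer density (first offender: region "
            f"{table.region_labels[region]!r}, receptor "
            f"{table.receptor_labels[receptor]!r}, layer {LAYERS[layer]!r}); "
            "pass allow_missing=True to average available layers")
    return np.nanmean(dens, axis=2)


def normalize_columns(raw: np.ndarray, region_labels: Sequence[str],
                      receptor_labels: Sequence[str]) -> ReceptorMatrix:
    """Z-score each receptor column across regions (sample SD, ddof=1)."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] < 2:
        raise ValueError("need at least two regions to normalise")
    means = raw.mean(axis=0)
    sds = raw.std(axis=0, ddof=1)
    zero_var = np.where(sds == 0)[0]
    if zero_var.size:
        names = [receptor_labels[i] for i in zero_var]
        raise ValueError(f"zero-variance receptor column(s): {names}")
    return ReceptorMatrix(tuple(region_labels), tuple(receptor_labels),
                          (raw - means) / sds, means, sds)


def principal_components(matrix: ReceptorMatrix, k: int) -> PCBasis:
    """First k principal components of the normalised region × receptor
    matrix, regions as samples.

    Components are ordered by decreasing explained variance; each loading
    vector is sign-flipped so its largest-magnitude entry is positive
    (removing the eigenvector sign ambiguity).  ``explained_fraction``
    contains the per-component variance fractions relative to the total.
    """
    n_regions, n_receptors = matrix.values.shape
    k_max = min(n_regions - 1, n_receptors)
    if not 1 <= k <= k_max:
        raise ValueError(f"k must be in [1, {k_max}], got {k}")
    pca = PCA(n_components=k_max, svd_solver="full")
    scores_full = pca.fit_transform(matrix.values)
    loadings = pca.components_[:k].T.copy()       # receptors × k
    scores = scores_full[:, :k].copy()
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCBasis(loadings, scores,
                   pca.explained_variance_ratio_[:k].copy(),
                   matrix.region_labels, matrix.receptor_labels)


def map_channels_to_regions(channel_ids: Sequence[str],
                            channel_map: Mapping[str, str],
                            region_labels: Sequence[str],
                            region_values: np.ndarray) -> np.ndarray:
    """Look up per-region regressor values for each channel.

    ``region_values`` is regions × regressors, rows aligned with
    ``region_labels``; channels in the same region receive identical rows.
    """
    region_values = np.atleast_2d(np.asarray(region_values, dtype=float))
    if region_values.shape[0] != len(region_labels):
        raise ValueError("region_values rows must match region_labels")
    index = {r: i for i, r in enumerate(region_labels)}
    missing = [c for c in channel_ids
               if c not in channel_map or channel_map[c] not in index]
    if missing:
        raise KeyError(f"channels without a mapped region: {missing}")
    rows = [index[channel_map[c]] for c in channel_ids]
    return region_values[rows]


def build_design_matrix(channel_regressors: np.ndarray,
                        channel_ids: Sequence[str],
                        regressor_labels: Sequence[str] = (),
                        include_mean: bool = True) -> DesignMatrix:
    """Assemble the second-level design: ones column, then mean-centred
    regressors.

    A regressor that is constant across channels is kept (a warning is
    emitted) so that column bookkeeping stays aligned with the hypothesis.
    """
    X = np.atleast_2d(np.asarray(channel_regressors, dtype=float))
    if X.size == 0:
        X = np.empty((len(channel_ids), 0))
    if X.shape[0] != len(channel_ids):
        raise ValueError("row count must equal the number of channels")
    if X.shape[1] != len(regressor_labels):
        raise ValueError("regressor_labels must match regressor columns")
    centred = X - X.mean(axis=0)
    constant = np.where(X.std(axis=0) == 0)[0]
    if constant.size:
        import warnings
        names = [regressor_labels[i] for i in constant]
        warnings.warn(f"constant regressor column(s) retained: {names}")
    cols = [np.ones((X.shape[0], 1))] if include_mean else []
    cols.append(centred)
    labels = (("mean",) if include_mean else ()) + tuple(regressor_labels)
    return DesignMatrix(np.hstack(cols), labels, tuple(channel_ids))


def enumerate_receptor_subsets(
        receptors: Sequence[str] = ("AMPA", "NMDA", "GABA_A", "GABA_B"),
) -> list[tuple[str, ...]]:
    """All non-empty subsets of the candidate receptors, grouped by size.

    For the four canonical excitatory/inhibitory receptors this yields the
    15 designs: 4 singletons, 6 pairs, 4 triples and 1 full set.
    """
    receptors = tuple(receptors)
    subsets: list[tuple[str, ...]] = []
    for size in range(1, len(receptors) + 1):
        subsets.extend(combinations(receptors, size))
    return subsets
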