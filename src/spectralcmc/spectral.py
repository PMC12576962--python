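"""Periodic/aperiodic spectral summaries and channel selection.

iEEG power spectra mix band-limited oscillatory ("periodic") peaks with a
background power-law ("aperiodic", 1/f) trend.  This module separates the
two against a fixed generic reference line — intercept 1, slope −1 in
log10 space, i.e. power(f) = 10/f — applied to unit-total-power normalised
spectra, computes canonical band powers of the periodic residual, selects
the most periodic and most aperiodic channels, and smooths channel-ordered
summaries with a simple moving average.

The reference line is deliberately not fitted per channel: a single shared
line keeps the periodic residual comparable across channels (at the cost of
underestimating noise in the delta band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cmc

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "aperiodic_reference",
    "normalize_total_power",
    "periodic_component",
    "band_power",
    "select_top_periodic",
    "select_most_aperiodic",
    "aperiodic_mse",
    "smoothed_trend",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [low, high); gamma is closed at 60 Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError("band must satisfy 0 < low < high")

    def mask(self, grid: np.ndarray, closed_upper: bool = False) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        upper = grid <= self.high if closed_upper else grid < self.high
        return (grid >= self.low) & upper


#: delta, theta, alpha, beta, gamma; edges half-open so shared boundaries
#: (4, 8, 13, 30 Hz) are counted once, gamma closed at 60 Hz
CANONICAL_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 60.0),
)


def aperiodic_reference(grid: np.ndarray) -> np.ndarray:
    """The fixed fractional-noise line: log10 power = 1 − log10 f.

    Equivalently power(f) = 10/f, i.e. intercept 1 and slope −1 in
    logarithmic space.
    """
    grid = cmc.validate_grid(grid)
    return 10.0 ** (1.0 - np.log10(grid))


def normalize_total_power(psd: np.ndarray) -> np.ndarray:
    """Scale a spectrum to unit total power (sum over the grid)."""
    psd = np.asarray(psd, dtype=float)
    total = psd.sum()
    if total <= 0:
        raise ValueError("cannot normalise a zero-power spectrum")
    return psd / total


def periodic_component(psd: np.ndarray, grid: np.ndarray,
                       normalize: bool = True) -> np.ndarray:
    """Periodic residual: max(psd − reference, 0) pointwise.

    The spectrum is normalised to unit total power before subtraction (the
    reference line is likewise normalised over the same grid) so channels
    of different absolute power are comparable.  Frequencies where the
    power falls below the line are floored at zero.
    """
    grid = cmc.validate_grid(grid)
    psd = np.asarray(psd, dtype=float)
    if psd.shape != grid.shape:
        raise ValueError("psd and grid must have the same length")
    reference = aperiodic_reference(grid)
    if normalize:
        psd = normalize_total_power(psd)
        reference = normalize_total_power(reference)
    return np.maximum(psd - reference, 0.0)


def band_power(profile: np.ndarray, grid: np.ndarray,
               band: BandDefinition) -> float:
    """Sum of (periodic residual) power over the band's frequencies."""
    grid = cmc.validate_grid(grid)
    profile = np.asarray(profile, dtype=float)
    closed_upper = band.high >= grid[-1]
    mask = band.mask(grid, closed_upper=closed_upper)
    if not mask.any():
        raise ValueError(f"band {band.name!r} contains no grid frequencies")
    return float(profile[mask].sum())


def select_top_periodic(profiles: np.ndarray, grid: np.ndarray,
                        band: BandDefinition, channel_ids,
                        k: int = 10) -> list:
    """The k channels with the greatest periodic power in the band.

    Ties are broken by channel order.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    n = profiles.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available channels")
    powers = np.array([band_power(p, grid, band) for p in profiles])
    order = np.argsort(-powers, kind="stable")
    return [channel_ids[i] for i in order[:k]]


def aperiodic_mse(psd: np.ndarray, grid: np.ndarray) -> float:
    """MSE between the unit-power spectrum and the fractional-noise line."""
    grid = cmc.validate_grid(grid)
    p = normalize_total_power(np.asarray(psd, dtype=float))
    ref = normalize_total_power(aperiodic_reference(grid))
    return float(np.mean((p - ref) ** 2))


def select_most_aperiodic(psds: np.ndarray, grid: np.ndarray, channel_ids,
                          k: int = 10) -> list:
    """The k channels closest to the 1/f line over the full grid."""
    psds = np.atleast_2d(np.asarray(psds, dtype=float))
    n = psds.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available channels")
    errors = np.array([aperiodic_mse(p, grid) for p in psds])
    order = np.argsort(errors, kind="stable")
    return [channel_ids[i] for i in order[:k]]


def smoothed_trend(values: np.ndarray, window: int = 200) -> np.ndarray:
    """Centred simple moving average with truncated edge windows.

    ``values`` should already be ordered by the sort key of interest
    (e.g. ascending band power).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    n = values.size
    half = window // 2
    out = np.empty(n)
    cumsum = np.concatenate([[0.0], np.cumsum(values)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + (window % 2))
        out[i] = (cumsum[hi] - cumsum[lo]) / (hi - lo)
    return out
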