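"""Voxel-level markers: fALFF and ReHo.

fALFF (fractional amplitude of low-frequency fluctuation) is the fraction of
a voxel's spectral amplitude falling in a low-frequency band, a normalized
measure of how much of the signal's energy is slow fluctuation rather than
broadband noise. ReHo (regional homogeneity) quantifies local synchrony of a
voxel with its neighbors via Kendall's coefficient of concordance (KCC) over
their rank time courses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .datasets import VoxelDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FALFFConfig",
    "ReHoConfig",
    "MarkerMap",
    "compute_falff",
    "compute_kcc",
    "reho_map",
    "falff_map",
]


@dataclass(frozen=True)
class FALFFConfig:
    """Spectral band for the fALFF numerator.

    ``use_power=True`` sums the power spectrum instead of the amplitude
    (square-root-of-power) spectrum; amplitude is the field's convention and
    the default.
    """

    band_low: float = 0.009
    band_high: float = 0.08
    use_power: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("require 0 < band_low < band_high")


@dataclass(frozen=True)
class ReHoConfig:
    """Neighborhood definition for ReHo.

    ``K`` is the number of voxels in the concordance set: the voxel itself
    plus its 26 nearest (face, edge and corner) neighbors by default. Ties in
    the per-voxel rank time courses are resolved by midranks.
    """

    K: int = 27
    tie_rule: str = "midrank"

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.tie_rule != "midrank":
            raise ValueError("only midrank tie handling is implemented")


@dataclass
class MarkerMap:
    """Per-masked-voxel scalar marker values on a voxel grid."""

    values: np.ndarray  # (n_masked_voxels,), NaN = undefined
    marker: str  # "falff" | "reho"
    mask: np.ndarray  # boolean volume

    def volume(self) -> np.ndarray:
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = self.values
        return vol


def compute_falff(
    series: np.ndarray, fs: float, config: FALFFConfig = FALFFConfig()
) -> float:
    """Fraction of spectral amplitude in [band_low, band_high].

    The spectrum is the plain discrete Fourier transform of the full series
    (no tapering or segment averaging); the DC bin is excluded from both
    numerator and denominator. Returns a value in [0, 1]; an all-zero series
    yields 0 with a warning.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 8:
        raise ValueError("series must be 1-D with at least 8 samples")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    amp = np.abs(np.fft.rfft(series))[1:]  # drop DC
    if config.use_power:
        amp = amp**2
    freqs = np.fft.rfftfreq(series.size, d=1.0 / fs)[1:]
    total = amp.sum()
    if total == 0:
        logger.warning("all-zero series: fALFF defined as 0")
        return 0.0
    in_band = (freqs >= config.band_low) & (freqs <= config.band_high)
    return float(amp[in_band].sum() / total)


def compute_kcc(neighborhood: np.ndarray, config: ReHoConfig = ReHoConfig()) -> float:
    """Kendall's coefficient of concordance W over K rank time courses.

    With K series of length n, each series is ranked over time (midranks for
    ties), R_i is the sum of the K ranks at time point i, and

        W = (sum_i R_i^2 - n * Rbar^2) / ((1/12) K^2 (n^3 - n)),

    where Rbar = K (n + 1) / 2. W is 1 iff all K untied rankings agree. No
    tie correction is applied to the denominator; heavily tied data therefore
    cannot reach W = 1. A neighborhood of all-constant series has an
    undefined rank ordering and returns 0 with a warning.
    """
    arr = np.asarray(neighborhood, dtype=float)
    if arr.ndim != 2:
        raise ValueError("neighborhood must be 2-D (K series x n time points)")
    K, n = arr.shape
    if K < 2 or n < 2:
        raise ValueError(f"need K >= 2 and n >= 2, got K={K}, n={n}")
    if np.all(arr == arr[:, :1]):
        logger.warning("all series constant: KCC defined as 0")
        return 0.0
    ranks = rankdata(arr, axis=1)  # midranks
    R = ranks.sum(axis=0)  # (n,)
    Rbar = K * (n + 1) / 2.0
    num = np.sum(R**2) - n * Rbar**2
    den = (K**2) * (n**3 - n) / 12.0
    return float(num / den)


def _neighbor_offsets() -> np.ndarray:
    off = np.array(
        [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )
    return off


def reho_map(data: VoxelDataset, config: ReHoConfig = ReHoConfig()) -> MarkerMap:
    """Voxelwise KCC over the 3x3x3 neighborhood intersected with the mask.

    Interior voxels of a full mask use K = 27 (the voxel plus its 26
    neighbors); at mask edges K shrinks to the in-mask neighbor count. Voxels
    with fewer than 2 in-mask voxels in their neighborhood get NaN.
    """
    if data.n_voxels == 0:
        raise ValueError("empty mask")
    shape = data.mask.shape
    # map grid coordinate -> row index in data.series
    index_vol = np.full(shape, -1, dtype=int)
    index_vol[data.mask] = np.arange(data.n_voxels)
    coords = data.voxel_coords()
    offsets = _neighbor_offsets()
    ranks = rankdata(data.series, axis=1)
    values = np.full(data.n_voxels, np.nan)
    n = data.n_timepoints
    for row, (x, y, z) in enumerate(coords):
        nb = offsets + (x, y, z)
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        nb = nb[ok]
        idx = index_vol[nb[:, 0], nb[:, 1], nb[:, 2]]
        idx = idx[idx >= 0]
        K = idx.size
        if K < 2:
            continue
        r = ranks[idx]
        if np.all(data.series[idx] == data.series[idx][:, :1]):
            values[row] = 0.0
            continue
        R = r.sum(axis=0)
        Rbar = K * (n + 1) / 2.0
        num = np.sum(R**2) - n * Rbar**2
        den = (K**2) * (n**3 - n) / 12.0
        values[row] = num / den
    return MarkerMap(values=values, marker="reho", mask=data.mask)


def falff_map(
    data: VoxelDataset, fs: float, config: FALFFConfig = FALFFConfig()
) -> MarkerMap:
    """Voxelwise fALFF of the (full-spectrum) series in a dataset."""
    if data.n_voxels == 0:
        raise ValueError("empty mask")
    amp = np.abs(np.fft.rfft(data.series, axis=1))[:, 1:]
    if config.use_power:
        amp = amp**2
    freqs = np.fft.rfftfreq(data.n_timepoints, d=1.0 / fs)[1:]
    in_band = (freqs >= config.band_low) & (freqs <= config.band_high)
    total = amp.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(total > 0, amp[:, in_band].sum(axis=1) / total, 0.0)
    if np.any(total == 0):
        logger.warning("%d all-zero voxel series: fALFF set to 0", int((total == 0).sum()))
    return MarkerMap(values=values, marker="falff", mask=data.mask)
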