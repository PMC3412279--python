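"""Temporal preprocessing of BOLD series.

The canonical order for resting-state series is linear detrending, bandpass
filtering to the low-frequency band of interest, then nuisance regression.
:func:`preprocess_series` applies the three stages in that order and also
returns the pre-bandpass series, which downstream spectral-fraction markers
(fALFF) need: a bandpassed series has no out-of-band energy left, so the
fraction of total spectral amplitude in the band would be degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "detrend_linear",
    "bandpass",
    "regress_nuisance",
    "preprocess_series",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Temporal preprocessing parameters.

    Parameters
    ----------
    band_low, band_high : float
        Passband edges in Hz. The defaults (0.009, 0.08) bracket the
        low-frequency fluctuations carrying resting-state signal while
        excluding scanner drift below and respiratory/cardiac aliasing above.
    detrend : {"linear", "none"}
        Whether to remove the least-squares linear trend first.
    nuisance_names : list of str
        Labels of the nuisance covariate columns to regress out (motion-like
        and global-signal-like regressors in the subjects table).
    """

    band_low: float = 0.009
    band_high: float = 0.08
    detrend: str = "linear"
    nuisance_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 <= self.band_low < self.band_high:
            raise ValueError(
                f"require 0 <= band_low < band_high, got "
                f"({self.band_low}, {self.band_high})"
            )
        if self.detrend not in ("linear", "none"):
            raise ValueError(f"unknown detrend mode {self.detrend!r}")


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (slope and intercept).

    Operates along the last axis; accepts 1-D series or stacked 2-D
    (signals x time) arrays.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 3:
        raise ValueError(f"need at least 3 time points, got {series.shape[-1]}")
    return signal.detrend(series, axis=-1, type="linear")


def _butter_band(band_low: float, band_high: float, fs: float):
    if fs <= 2.0 * band_high:
        raise ValueError(
            f"sampling rate {fs} Hz must exceed twice the upper band edge "
            f"{band_high} Hz"
        )
    nyq = fs / 2.0
    if band_low <= 0:
        return signal.butter(4, band_high / nyq, btype="lowpass", output="sos")
    return signal.butter(
        4, [band_low / nyq, band_high / nyq], btype="bandpass", output="sos"
    )


def bandpass(
    series: np.ndarray, config: PreprocessConfig, fs: float
) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis.

    A forward-backward (zero-phase) order-4 Butterworth filter with
    even-reflection padding of one series length, so short series (a few
    hundred volumes) do not carry start-up transients into the estimate.
    """
    series = np.asarray(series, dtype=float)
    sos = _butter_band(config.band_low, config.band_high, fs)
    n = series.shape[-1]
    padlen = min(n - 1, 3 * n // 4 * 4)  # reflection padding, < series length
    return signal.sosfiltfilt(sos, series, axis=-1, padtype="even", padlen=padlen)


def regress_nuisance(series: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Project out nuisance covariates (plus an intercept) from a series.

    Parameters
    ----------
    series : array, shape (T,) or (n_signals, T)
    covariates : array, shape (T, k)

    Returns
    -------
    residuals with the same shape as ``series``, orthogonal to every
    covariate column and to the constant.
    """
    series = np.asarray(series, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    T = series.shape[-1]
    if covariates.shape[0] != T:
        raise ValueError(
            f"covariates have {covariates.shape[0]} rows but series has "
            f"{T} time points"
        )
    if covariates.shape[1] >= T:
        raise ValueError("more covariates than time points")
    X = np.column_stack([np.ones(T), covariates])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning(
            "nuisance design is rank deficient (rank %d < %d columns); "
            "dependent columns contribute nothing to the fit",
            rank,
            X.shape[1],
        )
    Y = np.atleast_2d(series).T  # (T, n_signals)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T
    return resid.reshape(series.shape)


def preprocess_series(
    series: np.ndarray,
    config: PreprocessConfig,
    fs: float,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run detrend -> bandpass -> nuisance regression.

    Returns
    -------
    (banded, fullspec) : tuple of arrays
        ``banded`` is the fully preprocessed series feeding synchrony and
        connectivity measures. ``fullspec`` skips the bandpass (detrended and
        nuisance-regressed only) and is the input for spectral-fraction
        markers.
    """
    x = np.asarray(series, dtype=float)
    if config.detrend == "linear":
        x = detrend_linear(x)
    banded = bandpass(x, config, fs)
    fullspec = x
    if covariates is not None and np.size(covariates):
        banded = regress_nuisance(banded, covariates)
        fullspec = regress_nuisance(fullspec, covariates)
    return banded, fullspec
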