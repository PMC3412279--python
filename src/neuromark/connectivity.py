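"""Region-level functional connectivity matrices.

Three complementary views of the same region x time data: Pearson
correlation of regional time courses (with the Fisher r-to-z
variance-stabilizing transform), partial correlation (dependence between two
regions after removing the linear influence of all others, read off the
normalized precision matrix), and spatial correlation (similarity of two
regions' whole-brain connectivity profiles, correlated across regions with
both self-entries excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import LedoitWolf

from .datasets import RegionDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "pearson_matrix",
    "fisher_z",
    "partial_matrix",
    "spatial_matrix",
]

KINDS = ("pearson_r", "pearson_z", "partial", "spatial")


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region matrix tagged by connectivity kind.

    ``pearson_r`` and ``partial`` carry 1 on the diagonal; ``pearson_z`` and
    ``spatial`` have an undefined self-entry stored as NaN.
    """

    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        finite = np.isfinite(v) & np.isfinite(v.T)
        if np.any(np.abs(np.where(finite, v - v.T, 0.0)) > 1e-10):
            raise ValueError("connectivity matrix is not symmetric")

    @property
    def region_count(self) -> int:
        return self.values.shape[0]

    def upper_values(self) -> np.ndarray:
        """Off-diagonal upper-triangle entries in row-major link order."""
        iu = np.triu_indices(self.region_count, k=1)
        return self.values[iu]


def pearson_matrix(data: RegionDataset) -> ConnectivityMatrix:
    """Product-moment correlation of regional time courses; diagonal 1."""
    x = data.series
    sd = x.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant region series at indices {bad.tolist()}")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=np.clip(r, -1.0, 1.0), kind="pearson_r")


def fisher_z(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Elementwise z = arctanh(r) off-diagonal; diagonal set to NaN."""
    if matrix.kind != "pearson_r":
        raise ValueError("fisher_z expects a pearson_r matrix")
    r = matrix.values.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        raise ValueError("off-diagonal |r| = 1: degenerate region pair")
    z = np.arctanh(r, where=off, out=np.zeros_like(r))
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(values=z, kind="pearson_z")


def partial_matrix(data: RegionDataset, shrinkage: str = "auto") -> ConnectivityMatrix:
    """Partial correlation from the inverse covariance (precision) matrix.

    rho_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj) with Omega the precision
    matrix; diagonal 1. With ``shrinkage="none"`` the sample covariance is
    inverted directly, which requires more time points than regions and a
    well-conditioned estimate. ``"auto"`` applies Ledoit-Wolf analytic
    shrinkage whenever n_regions / n_timepoints > 0.25 (and always when the
    plain estimate would be singular), the standard stabilization for
    short-series, many-region data.
    """
    if shrinkage not in ("none", "auto"):
        raise ValueError("shrinkage must be 'none' or 'auto'")
    x = data.series
    n, T = x.shape
    use_shrinkage = shrinkage == "auto" and n / T > 0.25
    if shrinkage == "none" and T <= n:
        raise ValueError(
            f"T={T} <= n_regions={n}: sample covariance is singular; "
            "use shrinkage='auto'"
        )
    if use_shrinkage:
        cov = LedoitWolf(assume_centered=False).fit(x.T).covariance_
    else:
        cov = np.cov(x)
    try:
        omega = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        if shrinkage == "none":
            raise np.linalg.LinAlgError(
                "singular covariance; retry with shrinkage='auto'"
            ) from exc
        cov = LedoitWolf(assume_centered=False).fit(x.T).covariance_
        omega = np.linalg.inv(cov)
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return ConnectivityMatrix(values=np.clip(rho, -1.0, 1.0), kind="partial")


def spatial_matrix(zmat: ConnectivityMatrix) -> ConnectivityMatrix:
    """Correlation of two regions' connectivity profiles across regions.

    R_ij is the Pearson correlation of columns i and j of the Fisher-z
    connectivity matrix restricted to rows excluding both i and j, so that
    neither self-entry (z_ii, z_jj — undefined) nor the mutual entries
    (z_ij, z_ji) contribute. Pairs whose restricted profile has zero
    variance get NaN with a warning.
    """
    if zmat.kind != "pearson_z":
        raise ValueError("spatial_matrix expects a pearson_z matrix")
    z = zmat.values
    N = z.shape[0]
    if N < 4:
        raise ValueError("need at least 4 regions for spatial correlation")
    R = np.full((N, N), np.nan)
    n_degenerate = 0
    for i in range(N):
        for j in range(i + 1, N):
            keep = np.ones(N, dtype=bool)
            keep[[i, j]] = False
            a, b = z[keep, i], z[keep, j]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                n_degenerate += 1
                continue
            R[i, j] = R[j, i] = np.corrcoef(a, b)[0, 1]
    if n_degenerate:
        logger.warning(
            "%d region pairs had zero-variance restricted profiles "
            "(spatial correlation undefined)",
            n_degenerate,
        )
    return ConnectivityMatrix(values=R, kind="spatial")
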