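"""In-memory containers for per-subject imaging data.

A subject is represented at two scales: a :class:`RegionDataset` holds the
parcellated region-by-time matrix feeding connectivity measures, and a
:class:`VoxelDataset` holds the masked voxel grid feeding voxel-level markers
(local synchrony, spectral fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SubjectRecord", "RegionDataset", "VoxelDataset"]

GROUPS = ("control", "patient")


@dataclass
class SubjectRecord:
    """Identity, diagnosis, symptom severity and nuisance regressors.

    ``severity_index`` emulates a dimensional symptom score (e.g. an ADHD
    rating-scale index); ``nuisance`` is a time x k matrix of motion-like and
    global-signal-like regressors removed during preprocessing.
    """

    subject_id: str
    group: str
    severity_index: float
    nuisance: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")


@dataclass
class RegionDataset:
    """Region x time matrix of parcellated BOLD signals."""

    series: np.ndarray  # (n_regions, n_timepoints)

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError("region series must be 2-D (regions x time)")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("region series contain non-finite values")

    @property
    def n_regions(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


@dataclass
class VoxelDataset:
    """Masked voxel grid with per-voxel time series.

    ``labels`` assigns each in-mask voxel to a region (0 marks voxels outside
    the mask). ``series`` stores one time vector per masked voxel in the
    order given by ``np.flatnonzero(mask.ravel())``.
    """

    grid_shape: tuple[int, int, int]
    mask: np.ndarray  # boolean volume
    labels: np.ndarray  # integer volume, 0 = outside mask
    series: np.ndarray  # (n_masked_voxels, n_timepoints)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.labels = np.asarray(self.labels, dtype=int)
        self.series = np.asarray(self.series, dtype=float)
        if self.mask.shape != tuple(self.grid_shape):
            raise ValueError("mask shape does not match grid_shape")
        if self.labels.shape != tuple(self.grid_shape):
            raise ValueError("labels shape does not match grid_shape")
        if np.any((self.labels > 0) & ~self.mask):
            raise ValueError("labeled voxel found outside the mask")
        if self.series.shape[0] != int(self.mask.sum()):
            raise ValueError(
                f"{self.series.shape[0]} series for {int(self.mask.sum())} "
                "masked voxels"
            )

    @property
    def n_voxels(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]

    def voxel_coords(self) -> np.ndarray:
        """(n_voxels, 3) integer grid coordinates of masked voxels."""
        return np.argwhere(self.mask)

    def series_volume(self) -> np.ndarray:
        """Scatter series back to a 4-D (x, y, z, t) volume, zeros outside."""
        vol = np.zeros(self.mask.shape + (self.n_timepoints,))
        vol[self.mask] = self.series
        return vol
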