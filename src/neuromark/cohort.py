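"""Synthetic two-group cohorts with planted, parameterized group effects.

The generator emulates the statistical structure a resting-state
classification pipeline consumes, at desk scale:

* region-level BOLD-like signals: multivariate normal draws with a specified
  covariance, spectrally shaped into the low-frequency band (0.009-0.08 Hz)
  typical of resting-state fluctuations;
* planted continuous connectivity differences (``planted_corr_links``):
  entries added to the patient group's region covariance;
* planted occurrence differences (``planted_occurrence_links``): a
  link-specific shared component included per subject with group-dependent
  Bernoulli probability, giving link "presence" the binomial sampling model
  the occurrence association test assumes;
* planted local-synchrony differences (``planted_reho_regions``): patients'
  voxels in a region share a larger common-signal fraction;
* planted spectral differences (``planted_falff_regions``): patients'
  voxels in a region gain extra in-band (positive delta) or out-of-band
  (negative delta) power;
* a severity index linearly coupled to each patient's realized effect
  magnitude, so markers that are weaker in patients correlate negatively
  with severity.

Regions are laid out as separated cuboid voxel blocks on a 4 mm isotropic
grid, so voxel neighborhoods never straddle two regions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
from scipy import signal

from .datasets import RegionDataset, SubjectRecord, VoxelDataset

__all__ = [
    "CohortSpec",
    "SubjectData",
    "generate_cohort",
    "embed_voxels",
    "region_layout",
    "high_effect_spec",
    "null_spec",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    Sizes and planted effects; ``seed`` makes generation bit-reproducible.
    Defaults follow a typical resting-state acquisition: 231 retained
    volumes at a 2 s sampling interval on a 4 mm isotropic grid. The
    severity model places controls at ``severity_base`` and patients at
    ``severity_base + severity_gain * (realized mean planted effect)``, both
    plus Gaussian noise; defaults reproduce dimensional symptom scores with
    control/patient group means near 29/50.
    """

    n_controls: int = 141
    n_patients: int = 98
    n_regions: int = 20
    voxels_per_region: int = 27
    n_timepoints: int = 231
    sampling_interval: float = 2.0
    planted_corr_links: tuple[tuple[int, int, float], ...] = ()
    planted_occurrence_links: tuple[tuple[int, int, float, float], ...] = ()
    planted_reho_regions: tuple[tuple[int, float], ...] = ()
    planted_falff_regions: tuple[tuple[int, float], ...] = ()
    severity_base: float = 29.34
    severity_gain: float = 42.0
    severity_noise_sd: float = 6.41
    seed: int = 0
    # generative nuisance knobs (not group contrasts)
    base_sync: float = 0.5  # baseline shared-signal fraction within a region
    occurrence_strength: float = 0.5  # corr induced by a present occurrence link
    effect_jitter_sd: float = 0.25  # per-subject scaling of planted effect sizes
    band_low: float = 0.009
    band_high: float = 0.08
    n_motion_regressors: int = 3

    def __post_init__(self) -> None:
        if self.n_controls < 0 or self.n_patients < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_controls + self.n_patients == 0:
            raise ValueError("cohort must contain at least one subject")
        if self.n_timepoints < 8:
            raise ValueError("n_timepoints must be >= 8")
        if self.n_regions < 1 or self.voxels_per_region < 1:
            raise ValueError("need at least one region and one voxel per region")
        for i, j, _d in self.planted_corr_links:
            self._check_region(i), self._check_region(j)
            if i == j:
                raise ValueError(f"corr link ({i},{j}) is a self-link")
        for i, j, pc, pp in self.planted_occurrence_links:
            self._check_region(i), self._check_region(j)
            if not (0 <= pc <= 1 and 0 <= pp <= 1):
                raise ValueError(
                    f"occurrence probabilities for link ({i},{j}) must lie "
                    f"in [0,1], got ({pc}, {pp})"
                )
        for r, _d in self.planted_reho_regions + self.planted_falff_regions:
            self._check_region(r)
        # the planted patient covariance must be positive definite
        _patient_covariance(self, effect_scale=1.0)

    def _check_region(self, r: int) -> None:
        if not 0 <= r < self.n_regions:
            raise ValueError(
                f"region index {r} out of range for {self.n_regions} regions"
            )

    @property
    def fs(self) -> float:
        return 1.0 / self.sampling_interval

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


class SubjectData(NamedTuple):
    record: SubjectRecord
    voxels: VoxelDataset
    regions: RegionDataset


def _patient_covariance(spec: CohortSpec, effect_scale: float) -> np.ndarray:
    """Region covariance for a patient with per-subject effect scaling.

    Raises a ValueError naming the offending links if the group-level target
    (effect_scale = 1) is not positive definite.
    """
    cov = np.eye(spec.n_regions)
    for i, j, d in spec.planted_corr_links:
        cov[i, j] += d * effect_scale
        cov[j, i] += d * effect_scale
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        if effect_scale == 1.0:
            raise ValueError(
                "planted_corr_links "
                f"{[(i, j, d) for i, j, d in spec.planted_corr_links]} give a "
                "non-positive-definite region covariance"
            ) from None
        raise
    return cov


def _subject_covariance(spec: CohortSpec, g: float) -> np.ndarray:
    """Patient covariance at jitter g, shrinking g toward 1 until PD."""
    for _ in range(60):
        try:
            return _patient_covariance(spec, effect_scale=g)
        except np.linalg.LinAlgError:
            g = 1.0 + 0.5 * (g - 1.0)
    return _patient_covariance(spec, effect_scale=1.0)


def _band_sos(spec: CohortSpec):
    nyq = spec.fs / 2.0
    return signal.butter(
        4, [spec.band_low / nyq, spec.band_high / nyq], btype="bandpass",
        output="sos",
    )


def _band_noise(sos, shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Unit-variance bandlimited noise along the last axis."""
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def region_layout(spec: CohortSpec) -> tuple[tuple[int, int, int], np.ndarray, np.ndarray]:
    """Cuboid region blocks separated by one unmasked voxel.

    Returns (grid_shape, mask, labels). Labels are 1-based region numbers
    (region r -> label r + 1); 0 marks voxels outside the mask.
    """
    v = spec.voxels_per_region
    bx = int(np.ceil(v ** (1 / 3)))
    by = int(np.ceil(np.sqrt(v / bx)))
    bz = int(np.ceil(v / (bx * by)))
    n = spec.n_regions
    gx = int(np.ceil(n ** (1 / 3)))
    gy = int(np.ceil(np.sqrt(n / gx)))
    gz = int(np.ceil(n / (gx * gy)))
    shape = (gx * (bx + 1) + 1, gy * (by + 1) + 1, gz * (bz + 1) + 1)
    mask = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=int)
    r = 0
    for cx in range(gx):
        for cy in range(gy):
            for cz in range(gz):
                if r >= n:
                    break
                x0, y0, z0 = cx * (bx + 1) + 1, cy * (by + 1) + 1, cz * (bz + 1) + 1
                block = np.zeros(bx * by * bz, dtype=bool)
                block[:v] = True
                block = block.reshape(bx, by, bz)
                mask[x0:x0 + bx, y0:y0 + by, z0:z0 + bz] |= block
                lab = labels[x0:x0 + bx, y0:y0 + by, z0:z0 + bz]
                lab[block] = r + 1
                r += 1
    return shape, mask, labels


def embed_voxels(
    region_data: RegionDataset,
    spec: CohortSpec,
    *,
    group: str = "control",
    rng: np.random.Generator | None = None,
    effect_scale: float = 1.0,
) -> VoxelDataset:
    """Expand region series into a masked voxel grid.

    Each voxel mixes its region's signal with independent noise:
    ``sqrt(s) * region + sqrt(1 - s) * noise`` with s the shared-signal
    fraction (``base_sync``, raised or lowered by ``planted_reho_regions``
    for patients). For patients, ``planted_falff_regions`` add a
    region-shared in-band component (positive delta) or out-of-band
    component (negative delta) of variance |delta|.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if region_data.n_regions != spec.n_regions:
        raise ValueError("region count mismatch between data and spec")
    shape, mask, labels = region_layout(spec)
    sos = _band_sos(spec)
    T = region_data.n_timepoints
    reho_delta = dict()
    falff_delta = dict()
    if group == "patient":
        reho_delta = {r: d for r, d in spec.planted_reho_regions}
        falff_delta = {r: d for r, d in spec.planted_falff_regions}
    voxel_labels = labels[mask]  # per masked voxel, region label (1-based)
    series = np.empty((voxel_labels.size, T))
    # high-band shaping for negative spectral deltas: complement of the band
    nyq = spec.fs / 2.0
    sos_high = signal.butter(4, (2.5 * spec.band_high) / nyq, btype="highpass",
                             output="sos")
    for r in range(spec.n_regions):
        rows = np.flatnonzero(voxel_labels == r + 1)
        s = np.clip(spec.base_sync + reho_delta.get(r, 0.0) * effect_scale,
                    0.0, 1.0)
        base = region_data.series[r]
        sd = base.std() or 1.0
        noise = rng.standard_normal((rows.size, T))
        series[rows] = np.sqrt(s) * (base / sd) + np.sqrt(1.0 - s) * noise
        d = falff_delta.get(r, 0.0) * effect_scale
        if d > 0:
            extra = _band_noise(sos, (T,), rng)
            series[rows] += np.sqrt(d) * extra
        elif d < 0:
            extra = signal.sosfiltfilt(sos_high, rng.standard_normal(T))
            sd_e = extra.std() or 1.0
            series[rows] += np.sqrt(-d) * extra / sd_e
    return VoxelDataset(grid_shape=shape, mask=mask, labels=labels, series=series)


def _make_nuisance(
    spec: CohortSpec, region_series: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Motion-like AR(1) drifts plus a noisy global-mean regressor."""
    T = spec.n_timepoints
    k = spec.n_motion_regressors
    motion = np.empty((T, k))
    for c in range(k):
        e = rng.standard_normal(T)
        m = np.empty(T)
        m[0] = e[0]
        for t in range(1, T):
            m[t] = 0.95 * m[t - 1] + 0.1 * e[t]
        motion[:, c] = m
    global_like = region_series.mean(axis=0) + 0.1 * rng.standard_normal(T)
    return np.column_stack([motion, global_like[:, None]])


def generate_cohort(spec: CohortSpec) -> list[SubjectData]:
    """Draw the full cohort (controls first, then patients).

    Deterministic given ``spec`` (including its seed). Patients' region
    covariance carries the planted correlation deltas scaled by a
    per-subject jitter; occurrence links are included per subject by a
    Bernoulli draw at the group probability; the severity index is a linear
    function of the subject's realized mean planted effect plus noise.
    """
    rng = np.random.default_rng(spec.seed)
    sos = _band_sos(spec)
    control_chol = np.linalg.cholesky(np.eye(spec.n_regions))
    cohort: list[SubjectData] = []
    counts = (("control", spec.n_controls), ("patient", spec.n_patients))
    for group, n_subjects in counts:
        for s in range(n_subjects):
            if group == "patient":
                g = float(np.clip(
                    rng.normal(1.0, spec.effect_jitter_sd), 0.0, 2.0))
                chol = np.linalg.cholesky(_subject_covariance(spec, g))
            else:
                g = 0.0
                chol = control_chol
            raw = chol @ rng.standard_normal((spec.n_regions, spec.n_timepoints))
            x = signal.sosfiltfilt(sos, raw, axis=-1)
            sd = x.std(axis=-1, keepdims=True)
            sd[sd == 0] = 1.0
            x = x / sd
            effects: list[float] = []
            if group == "patient":
                effects += [abs(d) * g for _i, _j, d in spec.planted_corr_links]
                effects += [abs(d) * g for _r, d in spec.planted_reho_regions]
                effects += [abs(d) * g for _r, d in spec.planted_falff_regions]
            # occurrence links (drawn for both groups at the group probability)
            for i, j, p_control, p_patient in spec.planted_occurrence_links:
                p = p_patient if group == "patient" else p_control
                present = rng.random() < p
                c = spec.occurrence_strength
                u = _band_noise(sos, (3, spec.n_timepoints), rng)
                if present:
                    shared = u[0]
                    x[i] = np.sqrt(1 - c) * x[i] + np.sqrt(c) * shared
                    x[j] = np.sqrt(1 - c) * x[j] + np.sqrt(c) * shared
                else:
                    x[i] = np.sqrt(1 - c) * x[i] + np.sqrt(c) * u[1]
                    x[j] = np.sqrt(1 - c) * x[j] + np.sqrt(c) * u[2]
                if group == "patient":
                    toward_patient = present if p_patient >= p_control else not present
                    effects.append(abs(p_patient - p_control) * float(toward_patient))
            realized = float(np.mean(effects)) if effects else 0.0
            severity = (
                spec.severity_base
                + spec.severity_gain * realized
                + rng.normal(0.0, spec.severity_noise_sd)
            )
            regions = RegionDataset(series=x)
            voxels = embed_voxels(
                regions, spec, group=group, rng=rng,
                effect_scale=(g if group == "patient" else 1.0),
            )
            record = SubjectRecord(
                subject_id=f"{group[:3]}-{s:03d}",
                group=group,
                severity_index=float(severity),
                nuisance=_make_nuisance(spec, x, rng),
            )
            cohort.append(SubjectData(record, voxels, regions))
    return cohort


def high_effect_spec(
    n_controls: int = 50,
    n_patients: int = 50,
    n_regions: int = 20,
    voxels_per_region: int = 27,
    seed: int = 0,
) -> CohortSpec:
    """A strongly separable cohort: large planted effects of every kind."""
    return CohortSpec(
        n_controls=n_controls,
        n_patients=n_patients,
        n_regions=n_regions,
        voxels_per_region=voxels_per_region,
        seed=seed,
        planted_corr_links=((0, 1, 0.6), (2, 3, 0.6), (4, 5, -0.5)),
        planted_occurrence_links=((6, 7, 0.15, 0.85), (8, 9, 0.85, 0.15)),
        planted_reho_regions=((10, 0.35), (11, -0.30)),
        planted_falff_regions=((12, 1.5), (13, -1.5)),
    )


def null_spec(
    n_controls: int = 57,
    n_patients: int = 40,
    n_regions: int = 20,
    voxels_per_region: int = 27,
    seed: int = 0,
) -> CohortSpec:
    """A cohort with no planted group differences."""
    return CohortSpec(
        n_controls=n_controls,
        n_patients=n_patients,
        n_regions=n_regions,
        voxels_per_region=voxels_per_region,
        seed=seed,
    )


def write_cohort(cohort: list[SubjectData], spec: CohortSpec, outdir: str | Path) -> Path:
    """Write a cohort as NIfTI volumes plus a subjects table and spec sidecar.

    Per subject: ``<id>_bold.nii.gz`` (4-D voxel series, zeros outside the
    mask) and ``<id>_regions.tsv`` (region x time matrix). Shared:
    ``labels.nii.gz`` (integer parcellation), ``subjects.tsv`` and
    ``cohort_spec.json``.
    """
    import nibabel as nib
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([4.0, 4.0, 4.0, 1.0])  # 4 mm isotropic
    labels_img = nib.Nifti1Image(
        cohort[0].voxels.labels.astype(np.int16), affine
    )
    nib.save(labels_img, outdir / "labels.nii.gz")
    rows = []
    for record, voxels, regions in cohort:
        vol = voxels.series_volume().astype(np.float32)
        nib.save(nib.Nifti1Image(vol, affine), outdir / f"{record.subject_id}_bold.nii.gz")
        pd.DataFrame(regions.series).to_csv(
            outdir / f"{record.subject_id}_regions.tsv", sep="\t",
            header=False, index=False,
        )
        row = {
            "subject_id": record.subject_id,
            "group": record.group,
            "severity_index": record.severity_index,
        }
        for c in range(record.nuisance.shape[1]):
            row[f"nuisance_{c}"] = record.nuisance[:, c].tolist()
        rows.append(row)
    table = pd.DataFrame(
        [{k: v for k, v in r.items() if not isinstance(v, list)} for r in rows]
    )
    table.to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    np.savez_compressed(
        outdir / "nuisance.npz",
        **{r["subject_id"]: np.array(
            [r[f"nuisance_{c}"] for c in range(cohort[0].record.nuisance.shape[1])]
        ).T for r in rows},
    )
    (outdir / "cohort_spec.json").write_text(spec.to_json())
    return outdir


def load_cohort(indir: str | Path) -> tuple[list[SubjectData], CohortSpec]:
    """Read a cohort directory written by :func:`write_cohort`.

    Accepts the same layout for user-supplied data: per-subject 4-D NIfTI
    volumes plus ``labels.nii.gz`` (integer parcellation), ``subjects.tsv``
    (subject_id, group, severity_index) and optional ``nuisance.npz``;
    region series are read from ``<id>_regions.tsv`` when present, otherwise
    computed as mean series over each parcellation label.
    """
    import nibabel as nib
    import pandas as pd

    indir = Path(indir)
    table = pd.read_csv(indir / "subjects.tsv", sep="\t")
    labels = np.asarray(nib.load(indir / "labels.nii.gz").dataobj).astype(int)
    mask = labels > 0
    spec_path = indir / "cohort_spec.json"
    spec = None
    if spec_path.exists():
        d = json.loads(spec_path.read_text())
        for key in ("planted_corr_links", "planted_occurrence_links",
                    "planted_reho_regions", "planted_falff_regions"):
            d[key] = tuple(tuple(x) for x in d.get(key, ()))
        spec = CohortSpec(**d)
    nuisance_path = indir / "nuisance.npz"
    nuisance = np.load(nuisance_path) if nuisance_path.exists() else None
    cohort: list[SubjectData] = []
    for _, row in table.iterrows():
        sid = row["subject_id"]
        vol = np.asarray(nib.load(indir / f"{sid}_bold.nii.gz").dataobj,
                         dtype=float)
        series = vol[mask]
        voxels = VoxelDataset(
            grid_shape=labels.shape, mask=mask, labels=labels, series=series
        )
        regions_tsv = indir / f"{sid}_regions.tsv"
        if regions_tsv.exists():
            reg = pd.read_csv(regions_tsv, sep="\t", header=None).to_numpy()
        else:
            n_regions = labels.max()
            voxel_labels = labels[mask]
            reg = np.vstack(
                [series[voxel_labels == r + 1].mean(axis=0)
                 for r in range(n_regions)]
            )
        nui = (
            np.asarray(nuisance[sid]) if nuisance is not None and sid in nuisance
            else np.zeros((series.shape[1], 0))
        )
        record = SubjectRecord(
            subject_id=str(sid),
            group=str(row["group"]),
            severity_index=float(row["severity_index"]),
            nuisance=nui,
        )
        cohort.append(SubjectData(record, voxels, RegionDataset(series=reg)))
    if spec is None:
        n_regions = int(labels.max())
        spec = CohortSpec(
            n_controls=int((table["group"] == "control").sum()),
            n_patients=int((table["group"] == "patient").sum()),
            n_regions=n_regions,
            voxels_per_region=max(1, int(mask.sum()) // max(n_regions, 1)),
            n_timepoints=cohort[0].regions.n_timepoints,
        )
    return cohort, spec
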