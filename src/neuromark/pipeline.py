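"""End-to-end orchestration: cohort -> preprocessing -> markers ->
connectivity -> occurrence testing -> fold-wise classification -> reports.

The stages are the library modules; this module wires them together on a
cohort, assembles the wide per-subject feature matrix consumed by the
fold-wise integrators, and persists intermediate tables for audit. All
randomness flows from the seed recorded in the run configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bwas as bwas_mod
from .classify import KernelConfig, loocv_evaluate
from .cohort import CohortSpec, SubjectData, generate_cohort, write_cohort
from .connectivity import fisher_z, partial_matrix, pearson_matrix, spatial_matrix
from .datasets import RegionDataset, VoxelDataset
from .features import (
    ClusterCorrectionConfig,
    FeatureIntegrator,
    FeatureLayout,
    severity_association,
)
from .markers import FALFFConfig, ReHoConfig, falff_map, reho_map
from .preprocess import PreprocessConfig, preprocess_series

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "featurize_cohort",
    "run_simulate",
    "run_full",
    "run_sweep",
]


@dataclass(frozen=True)
class RunConfig:
    """One reproducible run: cohort, stage configs, selection threshold, seed."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    falff: FALFFConfig = field(default_factory=FALFFConfig)
    reho: ReHoConfig = field(default_factory=ReHoConfig)
    bwas: bwas_mod.BWASConfig = field(default_factory=bwas_mod.BWASConfig)
    cluster: ClusterCorrectionConfig = field(default_factory=ClusterCorrectionConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    p_threshold: float = 0.008
    partial_shrinkage: str = "auto"
    binarize_rule: str = "significance"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = {}
        sub = {
            "cohort": CohortSpec,
            "preprocess": PreprocessConfig,
            "falff": FALFFConfig,
            "reho": ReHoConfig,
            "bwas": bwas_mod.BWASConfig,
            "cluster": ClusterCorrectionConfig,
            "kernel": KernelConfig,
        }
        for key, val in d.items():
            if key in sub:
                if key == "kernel":
                    for g in ("C_grid", "gamma_grid"):
                        if g in val:
                            val[g] = tuple(val[g])
                if key == "cohort":
                    for g in (
                        "planted_corr_links",
                        "planted_occurrence_links",
                        "planted_reho_regions",
                        "planted_falff_regions",
                    ):
                        if g in val:
                            val[g] = tuple(tuple(x) for x in val[g])
                kw[key] = sub[key](**val)
            else:
                kw[key] = val
        return cls(**kw)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FeaturizedCohort:
    """Wide per-subject feature matrix plus its column layout and metadata."""

    X: np.ndarray
    y: np.ndarray
    severity: np.ndarray
    subject_ids: list[str]
    layout: FeatureLayout
    nets: bwas_mod.BinaryNetworkSet


def _preprocess_subject(
    sub: SubjectData, config: PreprocessConfig, fs: float
) -> tuple[RegionDataset, VoxelDataset, VoxelDataset]:
    """Returns (banded regions, banded voxels, full-spectrum voxels)."""
    cov = sub.record.nuisance if sub.record.nuisance.size else None
    region_band, _ = preprocess_series(sub.regions.series, config, fs, cov)
    voxel_band, voxel_full = preprocess_series(sub.voxels.series, config, fs, cov)
    v = sub.voxels
    mk = lambda s: VoxelDataset(
        grid_shape=v.grid_shape, mask=v.mask, labels=v.labels, series=s
    )
    return RegionDataset(series=region_band), mk(voxel_band), mk(voxel_full)


def featurize_cohort(
    cohort: list[SubjectData], config: RunConfig
) -> FeaturizedCohort:
    """Preprocess every subject and assemble the wide feature matrix.

    Columns: ReHo voxels | fALFF voxels | Pearson-z links | spatial links |
    partial links | partial-link presence. Link blocks are upper-triangle,
    row-major. Only subject-level quantities are computed here; everything
    group-dependent (selection, integration) happens fold-wise downstream.
    """
    fs = config.cohort.fs
    rows = []
    partial_mats = []
    for sub in cohort:
        t0 = time.perf_counter()
        regions_b, voxels_b, voxels_f = _preprocess_subject(
            sub, config.preprocess, fs
        )
        reho = reho_map(voxels_b, config.reho).values
        falff = falff_map(voxels_f, fs, config.falff).values
        r = pearson_matrix(regions_b)
        z = fisher_z(r)
        sp = spatial_matrix(z)
        pc = partial_matrix(regions_b, shrinkage=config.partial_shrinkage)
        partial_mats.append(pc)
        rows.append((reho, falff, z.upper_values(), sp.upper_values(),
                     pc.upper_values()))
        logger.debug(
            "featurized %s in %.2fs", sub.record.subject_id,
            time.perf_counter() - t0,
        )
    labels = np.array([sub.record.group for sub in cohort])
    # bandpassed series carry far fewer independent samples than time points;
    # for an ideally bandlimited process T_eff ~ T x bandwidth / Nyquist
    band = config.preprocess
    t_eff = int(
        config.cohort.n_timepoints
        * (band.band_high - band.band_low)
        / (fs / 2.0)
    )
    nets = bwas_mod.binarize_networks(
        partial_mats,
        labels,
        rule=config.binarize_rule,
        n_timepoints=config.cohort.n_timepoints,
        n_effective=t_eff,
    )
    X = np.hstack(
        [
            np.vstack([r[0] for r in rows]),
            np.vstack([r[1] for r in rows]),
            np.vstack([r[2] for r in rows]),
            np.vstack([r[3] for r in rows]),
            np.vstack([r[4] for r in rows]),
            nets.presence.astype(float),
        ]
    )
    n_regions = cohort[0].regions.n_regions
    layout = FeatureLayout(
        n_voxels=cohort[0].voxels.n_voxels,
        n_links=n_regions * (n_regions - 1) // 2,
        n_regions=n_regions,
        grid_mask=cohort[0].voxels.mask,
    )
    return FeaturizedCohort(
        X=X,
        y=labels,
        severity=np.array([sub.record.severity_index for sub in cohort]),
        subject_ids=[sub.record.subject_id for sub in cohort],
        layout=layout,
        nets=nets,
    )


def run_simulate(config: RunConfig, outdir: str | Path) -> Path:
    """Generate the cohort and write it (NIfTI + tables + spec sidecar)."""
    cohort = generate_cohort(config.cohort)
    path = write_cohort(cohort, config.cohort, outdir)
    manifest = {
        "n_subjects": len(cohort),
        "n_controls": config.cohort.n_controls,
        "n_patients": config.cohort.n_patients,
        "seed": config.cohort.seed,
    }
    (Path(path) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def _integrator_kwargs(config: RunConfig) -> dict:
    return {"bwas_config": config.bwas, "cluster_config": config.cluster}


def run_full(
    config: RunConfig,
    outdir: str | Path | None = None,
    cohort: list[SubjectData] | None = None,
) -> dict:
    """Execute the whole framework on one cohort.

    Returns a dict with the LOOCV classification report, the
    occurrence-association (BWAS) table over all subjects, group-level
    marker summaries, and marker-severity associations among patients. If
    ``outdir`` is given, every table is persisted as TSV/JSON.
    """
    t0 = time.perf_counter()
    if cohort is None:
        cohort = generate_cohort(config.cohort)
    feats = featurize_cohort(cohort, config)
    logger.info("featurized %d subjects in %.1fs", len(cohort),
                time.perf_counter() - t0)

    bwas_table = bwas_mod.run_bwas(feats.nets, config.bwas)

    report = loocv_evaluate(
        feats.X,
        feats.y,
        feats.layout,
        subject_ids=feats.subject_ids,
        p_threshold=config.p_threshold,
        kernel_config=config.kernel,
        integrator_kwargs=_integrator_kwargs(config),
        seed=config.seed,
    )

    # whole-cohort integration for the severity association (descriptive,
    # not part of the cross-validated classifier)
    integ = FeatureIntegrator(
        layout=feats.layout, p_threshold=config.p_threshold,
        **_integrator_kwargs(config),
    ).fit(feats.X, feats.y)
    F = integ.transform(feats.X)
    names = integ.feature_names_out()
    patients = feats.y == "patient"
    severity_rows = []
    for col, name in enumerate(names):
        vals = F[patients, col]
        if vals.std() == 0 or feats.severity[patients].std() == 0:
            continue
        r, p = severity_association(vals, feats.severity[patients])
        severity_rows.append({"feature": name, "r": r, "p": p})
    severity_table = pd.DataFrame(severity_rows)

    results = {
        "report": report,
        "bwas_table": bwas_table,
        "severity_table": severity_table,
        "integrated_features": pd.DataFrame(F, columns=names).assign(
            subject_id=feats.subject_ids, group=feats.y,
            severity=feats.severity,
        ),
        "elapsed_s": time.perf_counter() - t0,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "classification_report.json").write_text(report.to_json())
        bwas_table.to_csv(outdir / "bwas_links.tsv", sep="\t", index=False)
        severity_table.to_csv(outdir / "severity_association.tsv", sep="\t",
                              index=False)
        results["integrated_features"].to_csv(
            outdir / "integrated_features.tsv", sep="\t", index=False
        )
        folds = pd.DataFrame(report.fold_hyperparams)
        scalar_cols = [c for c in folds.columns if not c.endswith("_links")]
        folds[scalar_cols].to_csv(
            outdir / "fold_hyperparams.tsv", sep="\t", index=False
        )
        (outdir / "fold_artifacts.json").write_text(
            json.dumps(report.fold_hyperparams, indent=2)
        )
    logger.info(
        "full run: accuracy %.2f%% sensitivity %.2f%% specificity %.2f%% "
        "(%.1fs)",
        report.accuracy, report.sensitivity, report.specificity,
        results["elapsed_s"],
    )
    return results


def run_sweep(
    config: RunConfig,
    thresholds: list[float],
    outdir: str | Path | None = None,
    cohort: list[SubjectData] | None = None,
) -> pd.DataFrame:
    """LOOCV metrics as a function of the selection p-threshold."""
    if cohort is None:
        cohort = generate_cohort(config.cohort)
    feats = featurize_cohort(cohort, config)
    rows = []
    for thr in thresholds:
        report = loocv_evaluate(
            feats.X,
            feats.y,
            feats.layout,
            subject_ids=feats.subject_ids,
            p_threshold=thr,
            kernel_config=config.kernel,
            integrator_kwargs=_integrator_kwargs(config),
            seed=config.seed,
        )
        rows.append(
            {
                "p_threshold": thr,
                "accuracy": report.accuracy,
                "sensitivity": report.sensitivity,
                "specificity": report.specificity,
            }
        )
        logger.info("threshold %.4g: accuracy %.2f%%", thr, report.accuracy)
    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "threshold_sweep.tsv", sep="\t", index=False)
    return table
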