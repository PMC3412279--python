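"""Fold-wise feature selection and integration.

High-dimensional marker blocks (voxel maps, link matrices) are reduced to a
handful of per-subject scalars inside each cross-validation fold, using only
training subjects:

* two-sample t-tests at a p-threshold pick discriminative features, split by
  direction (increased vs decreased in patients), and the subject's values
  over each set are averaged (:class:`SignedMeanIntegrator`);
* the occurrence association test plays the same selecting role for the
  partial-correlation network (:class:`BWASSignedMean`);
* the Pearson-z link block is compressed by PCA on the selected links
  (:class:`PCAIntegrator`, m = 8 components by default);
* voxel maps are reduced to the mean over cluster-corrected significant
  voxels of one direction (:class:`MarkerMapIntegrator`), using a minimum
  cluster extent of 640 mm^3 at a voxel height threshold of p < 0.005.

All integrators follow the scikit-learn estimator contract (fit on training
rows only, transform any rows), so leakage safety is structural:
:class:`FeatureIntegrator` composes them into the full per-subject feature
vector used by the classifier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .bwas import BWASConfig, BinaryNetworkSet, bwas_test, link_counts

logger = logging.getLogger(__name__)

_emitted_warnings: set[str] = set()


def _warn_once(msg: str, *args) -> None:
    """Warn once per process for conditions recurring across CV folds."""
    key = msg % args if args else msg
    if key not in _emitted_warnings:
        _emitted_warnings.add(key)
        logger.warning(msg, *args)

__all__ = [
    "TTestSelection",
    "ttest_select",
    "integrate_signed_mean",
    "ClusterCorrectionConfig",
    "cluster_correct",
    "cluster_alpha_monte_carlo",
    "marker_means",
    "severity_association",
    "SignedMeanIntegrator",
    "PCAIntegrator",
    "BWASSignedMean",
    "MarkerMapIntegrator",
    "FeatureIntegrator",
    "FeatureLayout",
]


def _patient_mask(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "USO":
        return y == "patient"
    return y.astype(int) == 1


# ---------------------------------------------------------------------------
# t-test selection and signed means


@dataclass
class TTestSelection:
    """Per-feature two-sample t statistics with a threshold mask.

    ``sign`` is +1 where the patient mean exceeds the control mean
    (increased in patients), -1 otherwise.
    """

    t_score: np.ndarray
    p_value: np.ndarray
    selected: np.ndarray
    sign: np.ndarray


def ttest_select(
    train_features: np.ndarray,
    labels,
    p_threshold: float = 0.008,
    equal_var: bool = True,
) -> TTestSelection:
    """Two-sample (pooled by default) t-test per feature column.

    Features that are constant within both groups have an undefined t
    statistic and are never selected (warned once).
    """
    X = np.asarray(train_features, dtype=float)
    pat = _patient_mask(labels)
    if pat.sum() < 2 or (~pat).sum() < 2:
        raise ValueError("need at least 2 subjects per group in the training fold")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(X[pat], X[~pat], axis=0, equal_var=equal_var)
    bad = ~np.isfinite(p)
    if bad.any():
        logger.warning("%d zero-variance features excluded from selection", bad.sum())
        p = np.where(bad, 1.0, p)
        t = np.where(bad, 0.0, t)
    sign = np.where(X[pat].mean(axis=0) > X[~pat].mean(axis=0), 1, -1)
    return TTestSelection(
        t_score=t, p_value=p, selected=p < p_threshold, sign=sign
    )


def integrate_signed_mean(
    values: np.ndarray, selection: TTestSelection, warn: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Average a subject's values over the increased and decreased sets.

    ``values`` may be one subject's feature vector or a subjects x features
    matrix. An empty set contributes 0 (warned).
    """
    V = np.atleast_2d(np.asarray(values, dtype=float))
    up = selection.selected & (selection.sign > 0)
    down = selection.selected & (selection.sign < 0)
    out = []
    for mask, name in ((up, "increased"), (down, "decreased")):
        if mask.any():
            out.append(V[:, mask].mean(axis=1))
        else:
            if warn:
                logger.warning(
                    "no %s features selected: signed mean set to 0", name
                )
            out.append(np.zeros(V.shape[0]))
    up_mean, down_mean = out
    if np.asarray(values).ndim == 1:
        return float(up_mean[0]), float(down_mean[0])
    return up_mean, down_mean


# ---------------------------------------------------------------------------
# cluster-extent correction for voxel maps


@dataclass(frozen=True)
class ClusterCorrectionConfig:
    """Cluster-extent multiple-comparison control for voxel statistics.

    Suprathreshold voxels (uncorrected p below ``voxel_p``) are grouped into
    connected components; components smaller than
    ``ceil(min_cluster_volume / voxel_volume)`` voxels are discarded. The
    defaults (640 mm^3 at 64 mm^3 voxels => 10-voxel extent, voxel p <
    0.005) follow standard practice for 4 mm isotropic grids.
    """

    voxel_p: float = 0.005
    min_cluster_volume: float = 640.0
    voxel_volume: float = 64.0
    connectivity: int = 26
    mc_iterations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def min_voxels(self) -> int:
        return math.ceil(self.min_cluster_volume / self.voxel_volume)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


def cluster_correct(
    t_map: np.ndarray,
    df: int,
    config: ClusterCorrectionConfig = ClusterCorrectionConfig(),
    mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Extent-thresholded suprathreshold masks per sign.

    ``t_map`` is a 3-D volume of t statistics (NaN allowed outside the
    analysis mask). Returns boolean volumes ``{"increased": ...,
    "decreased": ...}`` keeping only connected components of at least the
    configured voxel extent.
    """
    t_map = np.asarray(t_map, dtype=float)
    if mask is None:
        mask = np.isfinite(t_map)
    p = 2.0 * stats.t.sf(np.abs(np.nan_to_num(t_map)), df)
    supra = (p < config.voxel_p) & mask
    out = {}
    struct = _structure(config.connectivity)
    for name, sign_mask in (
        ("increased", t_map > 0),
        ("decreased", t_map < 0),
    ):
        blob = supra & sign_mask
        lab, n = ndimage.label(blob, structure=struct)
        keep = np.zeros_like(blob)
        if n:
            sizes = np.bincount(lab.ravel())
            for comp in range(1, n + 1):
                if sizes[comp] >= config.min_voxels:
                    keep |= lab == comp
        out[name] = keep
    return out


def cluster_alpha_monte_carlo(
    grid_shape: tuple[int, int, int],
    mask: np.ndarray,
    config: ClusterCorrectionConfig,
    smooth_sigma: float = 1.0,
) -> float:
    """Achieved cluster-level alpha under a smoothed Gaussian null.

    Simulates ``mc_iterations`` smoothed white-noise volumes, thresholds at
    the voxel height threshold, and reports the fraction of iterations in
    which any cluster reaches the minimum extent — the family-wise error of
    the deterministic extent rule under this null.
    """
    if config.mc_iterations <= 0:
        raise ValueError("set mc_iterations > 0 for the Monte Carlo null")
    rng = np.random.default_rng(config.seed)
    struct = _structure(config.connectivity)
    z_thr = stats.norm.ppf(1.0 - config.voxel_p / 2.0)
    hits = 0
    for _ in range(config.mc_iterations):
        vol = ndimage.gaussian_filter(rng.standard_normal(grid_shape), smooth_sigma)
        vol = vol / vol[mask].std()
        supra = (np.abs(vol) > z_thr) & mask
        lab, n = ndimage.label(supra, structure=struct)
        if n and np.bincount(lab.ravel())[1:].max() >= config.min_voxels:
            hits += 1
    return hits / config.mc_iterations


def marker_means(
    maps_per_subject: np.ndarray,
    mask_volume: np.ndarray,
    grid_mask: np.ndarray,
    warn: bool = True,
) -> np.ndarray:
    """Mean marker value per subject over a significance mask.

    ``maps_per_subject`` is subjects x masked-voxels (ordering of
    ``grid_mask``); ``mask_volume`` is a boolean volume of significant
    voxels. Empty masks give 0 with a warning.
    """
    cols = mask_volume[grid_mask]
    if not cols.any():
        if warn:
            logger.warning("empty significance mask: marker mean set to 0")
        return np.zeros(np.atleast_2d(maps_per_subject).shape[0])
    return np.atleast_2d(maps_per_subject)[:, cols].mean(axis=1)


def severity_association(feature, severity) -> tuple[float, float]:
    """Pearson correlation (and two-sided p) between a marker and severity."""
    feature = np.asarray(feature, dtype=float)
    severity = np.asarray(severity, dtype=float)
    if feature.size != severity.size or feature.size < 3:
        raise ValueError("need matched vectors of at least 3 patients")
    if feature.std() == 0 or severity.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = stats.pearsonr(feature, severity)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# scikit-learn estimators


class SignedMeanIntegrator(TransformerMixin, BaseEstimator):
    """t-test selection + directional averaging of a feature block.

    ``fit(X, y)`` runs per-column two-sample t-tests on the training rows;
    ``transform(X)`` returns two columns per subject: the mean over features
    increased in patients and the mean over features decreased in patients.
    """

    def __init__(self, p_threshold: float = 0.008, equal_var: bool = True):
        self.p_threshold = p_threshold
        self.equal_var = equal_var

    def fit(self, X, y):
        self.selection_ = ttest_select(
            X, y, p_threshold=self.p_threshold, equal_var=self.equal_var
        )
        sel, sign = self.selection_.selected, self.selection_.sign
        for direction, m in (("increased", sel & (sign > 0)),
                             ("decreased", sel & (sign < 0))):
            if not m.any():
                _warn_once(
                    "no %s features selected: signed mean will be 0", direction
                )
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selection_")
        up, down = integrate_signed_mean(
            np.asarray(X, dtype=float), self.selection_, warn=False
        )
        return np.column_stack([up, down])


class PCAIntegrator(TransformerMixin, BaseEstimator):
    """t-test selection followed by PCA compression of the selected columns.

    Components are fitted on training rows only; test rows are projected
    with the training means and loadings. If fewer selected columns (or less
    rank) than ``m`` are available, missing components are zero-padded.
    """

    def __init__(self, m: int = 8, p_threshold: float = 0.008, equal_var: bool = True):
        self.m = m
        self.p_threshold = p_threshold
        self.equal_var = equal_var

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.m:
            raise ValueError(
                f"need at least m={self.m} training subjects, got {X.shape[0]}"
            )
        self.selection_ = ttest_select(
            X, y, p_threshold=self.p_threshold, equal_var=self.equal_var
        )
        cols = np.flatnonzero(self.selection_.selected)
        self.columns_ = cols
        k = min(self.m, cols.size, X.shape[0] - 1)
        if k < self.m:
            logger.warning(
                "rank %d < m=%d: trailing components zero-padded", k, self.m
            )
        if k > 0:
            self.pca_ = PCA(n_components=k).fit(X[:, cols])
            ev = np.zeros(self.m)
            ev[:k] = self.pca_.explained_variance_
        else:
            self.pca_ = None
            ev = np.zeros(self.m)
        self.explained_variance_ = ev
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "selection_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros((X.shape[0], self.m))
        if self.pca_ is not None:
            proj = self.pca_.transform(X[:, self.columns_])
            out[:, : proj.shape[1]] = proj
        return out


class BWASSignedMean(TransformerMixin, BaseEstimator):
    """Occurrence-test selection + directional averaging of link strengths.

    ``fit`` expects ``X`` with ``2 * n_links`` columns: the first half are
    continuous link strengths (e.g. partial correlations over upper-triangle
    links), the second half the corresponding binary presence indicators.
    Links whose occurrence test p-value (over training subjects) falls below
    ``p_threshold`` — and which survive the proportion floor/ceiling filter
    — are split by the sign of the occurrence difference: links more
    frequent in patients form the "up" set, links more frequent in controls
    the "down" set. ``transform`` averages the subject's strengths over each
    set.
    """

    def __init__(
        self,
        p_threshold: float = 0.008,
        config: BWASConfig = BWASConfig(),
        n_regions: int | None = None,
    ):
        self.p_threshold = p_threshold
        self.config = config
        self.n_regions = n_regions

    def _split(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] % 2:
            raise ValueError("expected strengths | presence concatenation")
        n_links = X.shape[1] // 2
        return X[:, :n_links], X[:, n_links:] > 0.5, n_links

    def fit(self, X, y):
        strengths, presence, n_links = self._split(X)
        n_regions = self.n_regions
        if n_regions is None:
            n_regions = int(round((1 + np.sqrt(1 + 8 * n_links)) / 2))
        pat = _patient_mask(y)
        labels = np.where(pat, "patient", "control")
        nets = BinaryNetworkSet(presence=presence, labels=labels, n_regions=n_regions)
        self.result_ = bwas_test(link_counts(nets), self.config)
        sel = (self.result_["p_value"] < self.p_threshold) & self.result_["retained"]
        s_hat = self.result_["S_hat"].to_numpy()
        self.up_links_ = np.flatnonzero(sel & (s_hat < 0))  # more frequent in patients
        self.down_links_ = np.flatnonzero(sel & (s_hat > 0))
        for name, links in (("up", self.up_links_), ("down", self.down_links_)):
            if not links.size:
                _warn_once(
                    "no %s occurrence links selected: mean will be 0", name
                )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "result_")
        strengths, _, _ = self._split(X)
        out = np.zeros((strengths.shape[0], 2))
        for c, links in enumerate((self.up_links_, self.down_links_)):
            if links.size:
                out[:, c] = strengths[:, links].mean(axis=1)
        return out


class MarkerMapIntegrator(TransformerMixin, BaseEstimator):
    """Cluster-corrected voxel t-map -> mean marker over one direction.

    ``fit`` runs a voxelwise two-sample t-test on the training rows, maps
    the statistics to the grid, applies the cluster-extent correction, and
    keeps the mask of the requested direction ("increased" or "decreased"
    in patients). ``transform`` averages each subject's map over that mask.
    """

    def __init__(
        self,
        grid_mask: np.ndarray,
        direction: str = "increased",
        cluster_config: ClusterCorrectionConfig = ClusterCorrectionConfig(),
        equal_var: bool = True,
    ):
        self.grid_mask = grid_mask
        self.direction = direction
        self.cluster_config = cluster_config
        self.equal_var = equal_var

    def fit(self, X, y):
        if self.direction not in ("increased", "decreased"):
            raise ValueError("direction must be 'increased' or 'decreased'")
        X = np.asarray(X, dtype=float)
        sel = ttest_select(X, y, p_threshold=1.1, equal_var=self.equal_var)
        t_vol = np.full(self.grid_mask.shape, np.nan)
        t_vol[self.grid_mask] = sel.t_score
        df = X.shape[0] - 2
        masks = cluster_correct(
            t_vol, df=df, config=self.cluster_config, mask=self.grid_mask
        )
        self.mask_ = masks[self.direction]
        if not self.mask_.any():
            _warn_once(
                "no surviving %s clusters: marker mean will be 0", self.direction
            )
        self.t_volume_ = t_vol
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mask_")
        return marker_means(
            np.asarray(X, dtype=float), self.mask_, self.grid_mask, warn=False
        )[:, None]


# ---------------------------------------------------------------------------
# the composed per-subject feature vector


@dataclass(frozen=True)
class FeatureLayout:
    """Column layout of the wide per-subject feature matrix.

    The matrix concatenates, per subject: ReHo voxels, fALFF voxels,
    Pearson-z links, spatial links, partial-correlation links, and binary
    presence indicators for the partial links. ``grid_mask`` maps voxel
    columns back to the 3-D grid for cluster correction.
    """

    n_voxels: int
    n_links: int
    n_regions: int
    grid_mask: np.ndarray

    @property
    def reho(self) -> slice:
        return slice(0, self.n_voxels)

    @property
    def falff(self) -> slice:
        return slice(self.n_voxels, 2 * self.n_voxels)

    @property
    def pearson_z(self) -> slice:
        a = 2 * self.n_voxels
        return slice(a, a + self.n_links)

    @property
    def spatial(self) -> slice:
        a = 2 * self.n_voxels + self.n_links
        return slice(a, a + self.n_links)

    @property
    def partial(self) -> slice:
        a = 2 * self.n_voxels + 2 * self.n_links
        return slice(a, a + self.n_links)

    @property
    def partial_presence(self) -> slice:
        a = 2 * self.n_voxels + 3 * self.n_links
        return slice(a, a + self.n_links)

    @property
    def n_columns(self) -> int:
        return 2 * self.n_voxels + 4 * self.n_links


FEATURE_NAMES = (
    "partial_up", "partial_down", "spatial_up", "spatial_down",
    *[f"pearson_pc{i + 1}" for i in range(8)],
    "reho_mean_increased", "falff_mean_decreased",
)


class FeatureIntegrator(TransformerMixin, BaseEstimator):
    """Full fold-wise selection + integration over a wide feature matrix.

    Produces, per subject: partial up/down means (occurrence-test
    selection), spatial up/down means (t-test selection), ``m`` principal
    components of the selected Pearson-z links, mean increased ReHo, and
    mean decreased fALFF — 2 + 2 + m + 2 columns.
    """

    def __init__(
        self,
        layout: FeatureLayout,
        p_threshold: float = 0.008,
        m: int = 8,
        bwas_config: BWASConfig = BWASConfig(),
        cluster_config: ClusterCorrectionConfig = ClusterCorrectionConfig(),
        equal_var: bool = True,
    ):
        self.layout = layout
        self.p_threshold = p_threshold
        self.m = m
        self.bwas_config = bwas_config
        self.cluster_config = cluster_config
        self.equal_var = equal_var

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        lay = self.layout
        if X.shape[1] != lay.n_columns:
            raise ValueError(
                f"X has {X.shape[1]} columns, layout expects {lay.n_columns}"
            )
        self.partial_ = BWASSignedMean(
            p_threshold=self.p_threshold,
            config=self.bwas_config,
            n_regions=lay.n_regions,
        ).fit(np.hstack([X[:, lay.partial], X[:, lay.partial_presence]]), y)
        self.spatial_ = SignedMeanIntegrator(
            p_threshold=self.p_threshold, equal_var=self.equal_var
        ).fit(X[:, lay.spatial], y)
        self.pearson_ = PCAIntegrator(
            m=self.m, p_threshold=self.p_threshold, equal_var=self.equal_var
        ).fit(X[:, lay.pearson_z], y)
        self.reho_ = MarkerMapIntegrator(
            grid_mask=lay.grid_mask,
            direction="increased",
            cluster_config=self.cluster_config,
            equal_var=self.equal_var,
        ).fit(X[:, lay.reho], y)
        self.falff_ = MarkerMapIntegrator(
            grid_mask=lay.grid_mask,
            direction="decreased",
            cluster_config=self.cluster_config,
            equal_var=self.equal_var,
        ).fit(X[:, lay.falff], y)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "partial_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lay = self.layout
        return np.hstack(
            [
                self.partial_.transform(
                    np.hstack([X[:, lay.partial], X[:, lay.partial_presence]])
                ),
                self.spatial_.transform(X[:, lay.spatial]),
                self.pearson_.transform(X[:, lay.pearson_z]),
                self.reho_.transform(X[:, lay.reho]),
                self.falff_.transform(X[:, lay.falff]),
            ]
        )

    def feature_names_out(self) -> tuple[str, ...]:
        return (
            "partial_up", "partial_down", "spatial_up", "spatial_down",
            *[f"pearson_pc{i + 1}" for i in range(self.m)],
            "reho_mean_increased", "falff_mean_decreased",
        )
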