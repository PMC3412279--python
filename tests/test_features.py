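import numpy as np
import pytest

from neuromark import RunConfig, featurize_cohort, generate_cohort
from neuromark.cohort import CohortSpec
from neuromark.features import (
    ClusterCorrectionConfig,
    FeatureIntegrator,
    MarkerMapIntegrator,
    PCAIntegrator,
    SignedMeanIntegrator,
    cluster_alpha_monte_carlo,
    cluster_correct,
    integrate_signed_mean,
    marker_means,
    severity_association,
    ttest_select,
)


class TestTTestSelect:
    def test_null_selection_rate_near_threshold(self, rng):
        X = rng.standard_normal((200, 2000))
        y = np.array(["control"] * 100 + ["patient"] * 100)
        sel = ttest_select(X, y, p_threshold=0.05)
        rate = sel.selected.mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 2000)

    def test_shifted_feature_selected_with_sign(self, rng):
        X = rng.standard_normal((100, 50))
        y = np.array(["control"] * 50 + ["patient"] * 50)
        X[50:, 7] += 3.0  # 3 pooled SDs
        sel = ttest_select(X, y, p_threshold=0.008)
        assert sel.selected[7]
        assert sel.sign[7] == 1

    def test_zero_threshold_selects_nothing(self, rng):
        X = rng.standard_normal((40, 10))
        y = np.array(["control"] * 20 + ["patient"] * 20)
        assert not ttest_select(X, y, p_threshold=0.0).selected.any()

    def test_zero_variance_feature_excluded(self, rng, caplog):
        X = rng.standard_normal((40, 5))
        X[:, 2] = 1.0
        y = np.array(["control"] * 20 + ["patient"] * 20)
        with caplog.at_level("WARNING"):
            sel = ttest_select(X, y, p_threshold=0.9)
        assert not sel.selected[2]
        assert "zero-variance" in caplog.text


class TestSignedMean:
    def _selection(self, selected, sign):
        from neuromark.features import TTestSelection

        selected = np.asarray(selected, dtype=bool)
        sign = np.asarray(sign)
        return TTestSelection(
            t_score=sign.astype(float), p_value=1.0 - selected.astype(float),
            selected=selected, sign=sign,
        )

    def test_single_selected_feature(self):
        sel = self._selection([True, False], [1, 1])
        up, down = integrate_signed_mean(np.array([0.7, 0.2]), sel)
        assert up == pytest.approx(0.7)
        assert down == 0.0

    def test_uniform_values_give_same_mean_both_directions(self):
        sel = self._selection([True, True, True, True], [1, 1, -1, -1])
        up, down = integrate_signed_mean(np.full(4, 3.14), sel)
        assert up == pytest.approx(3.14) and down == pytest.approx(3.14)

    def test_matches_loop_oracle(self, rng):
        values = rng.standard_normal(30)
        selected = rng.random(30) < 0.5
        sign = np.where(rng.random(30) < 0.5, 1, -1)
        sel = self._selection(selected, sign)
        up, down = integrate_signed_mean(values, sel)
        ups = [v for v, s, g in zip(values, selected, sign) if s and g > 0]
        downs = [v for v, s, g in zip(values, selected, sign) if s and g < 0]
        assert up == pytest.approx(np.mean(ups) if ups else 0.0, abs=1e-12)
        assert down == pytest.approx(np.mean(downs) if downs else 0.0, abs=1e-12)


class TestPCAIntegrator:
    def _labels(self, n):
        return np.array(["control", "patient"] * (n // 2))

    def test_rank_deficient_data_pads_zero_components(self, rng):
        base = rng.standard_normal((20, 2))
        X = base @ rng.standard_normal((2, 30))  # exact rank 2
        est = PCAIntegrator(m=8, p_threshold=1.1).fit(X, self._labels(20))
        assert np.allclose(est.explained_variance_[2:], 0.0, atol=1e-20)
        F = est.transform(X)
        assert F.shape == (20, 8)
        assert np.allclose(F[:, 2:], 0.0, atol=1e-8)

    def test_full_rank_projection_preserves_distances(self, rng):
        X = rng.standard_normal((30, 5))
        est = PCAIntegrator(m=5, p_threshold=1.1).fit(X, self._labels(30))
        F = est.transform(X)
        # complete basis: pairwise distances preserved (reconstruction error 0)
        d0 = np.linalg.norm(X[0] - X[1])
        assert np.linalg.norm(F[0] - F[1]) == pytest.approx(d0, abs=1e-8)

    def test_explained_variance_matches_eigvalue_oracle(self, rng):
        X = rng.standard_normal((40, 6))
        est = PCAIntegrator(m=6, p_threshold=1.1).fit(X, self._labels(40))
        cov = np.cov(X, rowvar=False, ddof=1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(est.explained_variance_, eig, atol=1e-10)

    def test_too_few_subjects_rejected(self, rng):
        X = rng.standard_normal((5, 10))
        with pytest.raises(ValueError, match="m=8"):
            PCAIntegrator(m=8).fit(X, self._labels(5)[:5])


class TestClusterCorrect:
    shape = (12, 12, 12)

    def _tmap(self, blobs):
        t = np.zeros(self.shape)
        for (x, y, z), size, val in blobs:
            flat = []
            # carve `size` voxels in a compact connected shape
            for dx in range(3):
                for dy in range(3):
                    for dz in range(3):
                        if len(flat) < size:
                            flat.append((x + dx, y + dy, z + dz))
            for c in flat:
                t[c] = val
        return t

    def test_large_blob_retained_small_rejected(self):
        t = self._tmap([((1, 1, 1), 12, 6.0), ((8, 8, 8), 5, 6.0)])
        masks = cluster_correct(t, df=100)
        lab_big = masks["increased"][1, 1, 1] or masks["increased"][2, 2, 2]
        assert masks["increased"].sum() == 12
        assert lab_big
        assert not masks["increased"][8, 8, 8]

    def test_sign_separation(self):
        t = self._tmap([((1, 1, 1), 12, 6.0), ((7, 7, 7), 12, -6.0)])
        masks = cluster_correct(t, df=100)
        assert masks["increased"].sum() == 12
        assert masks["decreased"].sum() == 12

    def test_white_noise_retains_nothing(self, rng):
        t = rng.standard_normal(self.shape)
        masks = cluster_correct(t, df=100)
        assert masks["increased"].sum() == 0
        assert masks["decreased"].sum() == 0

    def test_min_voxels_from_volume(self):
        cfg = ClusterCorrectionConfig(min_cluster_volume=640.0, voxel_volume=64.0)
        assert cfg.min_voxels == 10

    def test_monte_carlo_alpha_small_at_default_thresholds(self):
        cfg = ClusterCorrectionConfig(mc_iterations=100, seed=1)
        mask = np.ones((10, 10, 10), dtype=bool)
        alpha = cluster_alpha_monte_carlo((10, 10, 10), mask, cfg, smooth_sigma=0.8)
        assert alpha <= 0.1


class TestMarkerMeans:
    def test_single_voxel_mask(self, rng):
        grid_mask = np.ones((2, 2, 2), dtype=bool)
        maps = rng.standard_normal((3, 8))
        sig = np.zeros((2, 2, 2), dtype=bool)
        sig[0, 0, 0] = True
        out = marker_means(maps, sig, grid_mask)
        assert np.allclose(out, maps[:, 0])

    def test_uniform_map(self):
        grid_mask = np.ones((2, 2, 2), dtype=bool)
        sig = np.zeros((2, 2, 2), dtype=bool)
        sig[0, 0, :] = True
        out = marker_means(np.full((2, 8), 2.5), sig, grid_mask)
        assert np.allclose(out, 2.5)

    def test_matches_loop_oracle(self, rng):
        grid_mask = np.ones((3, 3, 3), dtype=bool)
        maps = rng.standard_normal((4, 27))
        sig = rng.random((3, 3, 3)) < 0.4
        out = marker_means(maps, sig, grid_mask)
        cols = [i for i, keep in enumerate(sig.ravel()) if keep]
        for s in range(4):
            expect = np.mean([maps[s, c] for c in cols]) if cols else 0.0
            assert out[s] == pytest.approx(expect, abs=1e-12)

    def test_empty_mask_warns_and_zeroes(self, rng, caplog):
        grid_mask = np.ones((2, 2, 2), dtype=bool)
        with caplog.at_level("WARNING"):
            out = marker_means(rng.standard_normal((3, 8)),
                               np.zeros((2, 2, 2), dtype=bool), grid_mask)
        assert np.allclose(out, 0.0)
        assert "empty" in caplog.text


class TestSeverityAssociation:
    def test_perfect_negative(self):
        sev = np.linspace(20, 60, 10)
        r, p = severity_association(-sev, sev)
        assert r == pytest.approx(-1.0)
        assert p < 1e-10

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(314159)
        r, _ = severity_association(rng.standard_normal(200),
                                    rng.standard_normal(200))
        assert abs(r) < 0.15

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            severity_association(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError):
            severity_association(np.arange(3.0), np.arange(4.0))


class TestMarkerRecoveryOnCohort:
    @pytest.fixture(scope="class")
    def reho_falff_cohort(self):
        spec = CohortSpec(
            n_controls=20, n_patients=20, n_regions=6, voxels_per_region=27,
            planted_reho_regions=((0, 0.35),),
            planted_falff_regions=((1, 1.5),),
            seed=17,
        )
        cohort = generate_cohort(spec)
        feats = featurize_cohort(cohort, RunConfig(cohort=spec))
        return spec, cohort, feats

    def _jaccard(self, a, b):
        return (a & b).sum() / (a | b).sum()

    def test_planted_reho_cluster_overlaps_region(self, reho_falff_cohort):
        spec, cohort, feats = reho_falff_cohort
        est = MarkerMapIntegrator(
            grid_mask=feats.layout.grid_mask, direction="increased"
        ).fit(feats.X[:, feats.layout.reho], feats.y)
        planted = cohort[0].voxels.labels == 1
        assert self._jaccard(est.mask_, planted) >= 0.5

    def test_planted_falff_cluster_overlaps_region(self, reho_falff_cohort):
        spec, cohort, feats = reho_falff_cohort
        # patients gained in-band power in region 1 -> increased direction
        est = MarkerMapIntegrator(
            grid_mask=feats.layout.grid_mask, direction="increased"
        ).fit(feats.X[:, feats.layout.falff], feats.y)
        planted = cohort[0].voxels.labels == 2
        assert self._jaccard(est.mask_, planted) >= 0.5


class TestFeatureIntegrator:
    def test_output_shape_and_names(self, small_featurized):
        f = small_featurized
        integ = FeatureIntegrator(layout=f.layout).fit(f.X, f.y)
        F = integ.transform(f.X)
        assert F.shape == (f.X.shape[0], 14)
        assert len(integ.feature_names_out()) == 14

    def test_training_artifacts_ignore_held_out_subject(self, small_featurized):
        """Leakage guard: mutating the held-out subject cannot change any
        training-fold selection artifact."""
        f = small_featurized
        train = np.ones(f.X.shape[0], dtype=bool)
        train[-1] = False
        integ1 = FeatureIntegrator(layout=f.layout).fit(f.X[train], f.y[train])
        X_mut = f.X.copy()
        X_mut[-1] = np.random.default_rng(0).permutation(X_mut[-1])
        integ2 = FeatureIntegrator(layout=f.layout).fit(X_mut[train], f.y[train])
        assert np.array_equal(integ1.reho_.mask_, integ2.reho_.mask_)
        assert np.array_equal(integ1.falff_.mask_, integ2.falff_.mask_)
        assert np.array_equal(integ1.partial_.up_links_, integ2.partial_.up_links_)
        assert np.array_equal(integ1.partial_.down_links_, integ2.partial_.down_links_)
        assert np.array_equal(
            integ1.spatial_.selection_.selected, integ2.spatial_.selection_.selected
        )
        assert np.array_equal(integ1.pearson_.columns_, integ2.pearson_.columns_)
        if integ1.pearson_.pca_ is not None:
            assert np.allclose(
                integ1.pearson_.pca_.components_, integ2.pearson_.pca_.components_
            )
        # and the transforms of the training rows agree exactly
        assert np.allclose(
            integ1.transform(f.X[train]), integ2.transform(X_mut[train])
        )

    def test_planted_effects_separate_groups(self, small_featurized):
        from scipy import stats

        f = small_featurized
        integ = FeatureIntegrator(layout=f.layout).fit(f.X, f.y)
        F = integ.transform(f.X)
        pat = f.y == "patient"
        # spatial up/down means carry the direction of their own selection
        assert F[pat, 2].mean() > F[~pat, 2].mean()  # spatial_up
        assert F[pat, 3].mean() < F[~pat, 3].mean()  # spatial_down
        # at least one integrated feature separates the groups strongly
        t, _ = stats.ttest_ind(F[pat], F[~pat], axis=0)
        assert np.nanmax(np.abs(t)) > 4.0
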